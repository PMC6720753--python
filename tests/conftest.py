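"""Shared fixtures: default scene, worked-example sequences, helpers."""

import math

import numpy as np
import pytest

from handtherm import synthetic as syn
from handtherm.pipeline import process_sequence


@pytest.fixture(scope="session")
def geometry():
    return syn.default_geometry()


@pytest.fixture(scope="session")
def label_map(geometry):
    return syn.render_label_map(geometry)


@pytest.fixture(scope="session")
def we_md_sequence(geometry):
    return syn.simulate_sequence(syn.subject_from_preset("WE-MD"), geometry)


@pytest.fixture(scope="session")
def we_hd_sequence(geometry):
    return syn.simulate_sequence(syn.subject_from_preset("WE-HD"), geometry)


@pytest.fixture(scope="session")
def we_md_processed(we_md_sequence):
    return process_sequence(we_md_sequence)


@pytest.fixture(scope="session")
def we_hd_processed(we_hd_sequence):
    return process_sequence(we_hd_sequence)


def point_in_capsule(finger: syn.FingerSpec, r: float, c: float) -> bool:
    """Ground-truth membership test for one finger capsule."""
    br, bc = finger.base
    tr, tc = finger.tip
    dr, dc = tr - br, tc - bc
    seg2 = dr * dr + dc * dc
    if seg2 == 0:
        d2 = (r - br) ** 2 + (c - bc) ** 2
    else:
        t = max(0.0, min(1.0, ((r - br) * dr + (c - bc) * dc) / seg2))
        d2 = (r - br - t * dr) ** 2 + (c - bc - t * dc) ** 2
    return d2 <= finger.half_width ** 2


def point_in_palm(geom: syn.HandGeometry, r: float, c: float) -> bool:
    pr, pc = geom.palm_center
    ar, ac = geom.palm_axes
    return ((r - pr) / ar) ** 2 + ((c - pc) / ac) ** 2 <= 1.0


FINGER_INDEX = {lab: i for i, lab in enumerate(syn.FINGER_LABELS)}
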