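import numpy as np
import pytest

from spinedyn.annotations import (
    ABSENT,
    PRESENT,
    ImagingSchedule,
    ROITimeSeries,
)

TOY_DAYS = (4, 7, 10)


def series_from_matrix(
    matrix,
    days=None,
    spine_ids=None,
    roi_id="roi1",
    mouse_id="m1",
    age="young",
    treatment="vehicle",
    segment_length=30.0,
    lengths=None,
    observed_days=None,
    treatment_window=(0, 28),
):
    """Build an ROITimeSeries from a boolean presence matrix (spines x
    sessions); every session is observed unless restricted."""
    matrix = np.asarray(matrix, dtype=bool)
    n, m = matrix.shape
    if days is None:
        days = tuple(range(1, m + 1))
    schedule = ImagingSchedule(tuple(days), treatment_window)
    if spine_ids is None:
        spine_ids = [f"s{i}" for i in range(n)]
    if observed_days is None:
        observed_days = days
    presence = np.where(matrix, PRESENT, ABSENT).astype(np.int8)
    return ROITimeSeries(
        roi_id=roi_id,
        mouse_id=mouse_id,
        age=age,
        treatment=treatment,
        schedule=schedule,
        spine_ids=spine_ids,
        segment_ids=["seg0"] * n,
        presence=presence,
        lengths=lengths,
        segment_lengths_um={"seg0": segment_length},
        observed_days=observed_days,
    )


@pytest.fixture
def toy_roi():
    """Three sessions t1=4, t2=7, t3=10: t1={A,B,C}, t2={A,B,D}, t3={A}."""
    matrix = np.array(
        [
            [1, 1, 1],  # A
            [1, 1, 0],  # B
            [1, 0, 0],  # C
            [0, 1, 0],  # D
        ],
        dtype=bool,
    )
    return series_from_matrix(
        matrix, days=TOY_DAYS, spine_ids=["A", "B", "C", "D"]
    )


def random_series(rng, n_spines=None, n_sessions=None, **kwargs):
    n = n_spines if n_spines is not None else int(rng.integers(1, 9))
    m = n_sessions if n_sessions is not None else int(rng.integers(2, 7))
    matrix = rng.random((n, m)) < 0.6
    return series_from_matrix(matrix, **kwargs)
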