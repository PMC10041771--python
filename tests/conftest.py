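import numpy as np
import pytest

from eupred.cohort import Cohort, CycleRecord, EmbryoRecord


def make_embryo(eid="e1", t2=25.0, t3=36.0, t4=38.0, t5=51.0, **kw):
    return EmbryoRecord(embryo_id=eid, t2=t2, t3=t3, t4=t4, t5=t5, **kw)


def make_cycle(cid="c1", age=33.0, n_sacs=0, n_embryos=1, couple=None, cycle_number=1, **kw):
    embryos = tuple(
        make_embryo(eid=f"{cid}-e{j + 1}", t2=25.0 + j, t3=36.0 + j, t4=38.0 + j, t5=51.0 + j)
        for j in range(n_embryos)
    )
    return CycleRecord(
        cycle_id=cid,
        female_age=age,
        embryos=embryos,
        n_sacs=n_sacs,
        couple_id=couple,
        cycle_number=cycle_number,
        **kw,
    )


def cohort_from_counts(set0, set1, det0, det1, det2, prefix="x"):
    """Minimal cohort realizing given outcome counts per transfer type."""
    cycles = []
    k = 0
    for n, sacs, m in (
        (set0, 0, 1),
        (set1, 1, 1),
        (det0, 0, 2),
        (det1, 1, 2),
        (det2, 2, 2),
    ):
        for _ in range(n):
            cycles.append(make_cycle(cid=f"{prefix}{k:05d}", n_sacs=sacs, n_embryos=m))
            k += 1
    return Cohort(cycles=cycles)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clinic_a_counts_cohort():
    """Cohort realizing the clinic-A outcome counts (SET 385/243, DET 53/21/4)."""
    return cohort_from_counts(385, 243, 53, 21, 4, prefix="a")


@pytest.fixture(scope="session")
def clinic_b_counts_cohort():
    return cohort_from_counts(536, 318, 137, 55, 18, prefix="b")


@pytest.fixture(scope="session")
def recovery_cohort():
    """clinic-A-like truth resized to n=2000 with 30% DET, one fixed seed."""
    from eupred.simulate import scenario_truth, simulate_cohort

    truth = scenario_truth("recovery")
    return truth, simulate_cohort(truth, seed=424242)
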