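"""SET-vs-DET decision support: embryo ranking and singleton/twin trade-offs.

For a candidate pair of embryos the report contrasts the best single
transfer (the higher of the two SET pregnancy probabilities) with the
double transfer: the gain in the chance of at least one gestational sac,
and the price paid as twin risk.  Under the EU model the twin probability
u*e1*e2 can never exceed either embryo's own SET probability, and adding
a second embryo can never lower the chance of pregnancy.  The output is
informational — probabilities, gain and risk — not a transfer
recommendation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cohort import Cohort, CycleRecord, MorphokineticFeatures, extract_features
from .model import EUModelFit, cycle_outcome_distribution, embryo_viability, receptivity

__all__ = ["TransferDecision", "rank_embryos", "det_tradeoff", "decision_table"]


@dataclass(frozen=True)
class TransferDecision:
    """Singleton/twin trade-off for one candidate embryo pair."""

    set_p1: float  # SET pregnancy probability, embryo 1
    set_p2: float
    det_p0: float
    det_singleton: float
    det_twin: float

    @property
    def det_pregnant(self) -> float:
        return self.det_singleton + self.det_twin

    @property
    def singleton_gain(self) -> float:
        """P(>= 1 sac | DET) minus the better SET probability."""
        return self.det_pregnant - max(self.set_p1, self.set_p2)

    @property
    def twin_risk(self) -> float:
        return self.det_twin


def rank_embryos(
    fit: EUModelFit,
    cycle: CycleRecord,
    features: Sequence[tuple[str, MorphokineticFeatures]] | None = None,
) -> list[tuple[str, float]]:
    """Embryos ordered by predicted SET pregnancy probability (descending).

    Ties are broken by embryo_id for determinism.  ``features`` overrides
    the cycle's own embryos with (embryo_id, features) pairs.
    """
    u = receptivity(fit, cycle)
    if features is None:
        ids = [e.embryo_id for e in cycle.transferred_embryos]
        feats = extract_features(cycle)
        features = list(zip(ids, feats))
    if not features:
        raise ValueError("no embryos with complete features to rank")
    scored = [(eid, u * embryo_viability(fit, f)) for eid, f in features]
    return sorted(scored, key=lambda kv: (-kv[1], kv[0]))


def det_tradeoff(
    fit: EUModelFit,
    cycle: CycleRecord,
    pair: tuple[MorphokineticFeatures, MorphokineticFeatures] | None = None,
) -> TransferDecision:
    """Trade-off report for transferring both embryos of a pair."""
    if pair is None:
        feats = extract_features(cycle)
        if len(feats) != 2:
            raise ValueError("cycle does not carry two feature-complete embryos")
        pair = (feats[0], feats[1])
    u = receptivity(fit, cycle)
    e1 = embryo_viability(fit, pair[0])
    e2 = embryo_viability(fit, pair[1])
    p0, p1, p2 = cycle_outcome_distribution(u, (e1, e2))
    return TransferDecision(
        set_p1=u * e1,
        set_p2=u * e2,
        det_p0=float(p0),
        det_singleton=float(p1),
        det_twin=float(p2),
    )


def decision_table(
    fit: EUModelFit, cohort: Cohort, min_set_chance: float = 0.0
) -> pd.DataFrame:
    """One row per DET-candidate cycle: top-two SET chances and DET outlook.

    Cycles must carry >= 2 feature-complete embryos.  ``min_set_chance``
    keeps only pairs where both embryos clear the SET-probability bar
    (e.g. 0.30 to mirror selecting pairs with at least a 30% chance each).
    """
    rows = []
    for cycle in cohort:
        feats = extract_features(cycle)
        if len(feats) < 2:
            continue
        ids = [e.embryo_id for e in cycle.transferred_embryos]
        ranked = rank_embryos(fit, cycle, features=list(zip(ids, feats)))
        (id1, p1), (id2, p2) = ranked[0], ranked[1]
        if min(p1, p2) < min_set_chance:
            continue
        by_id = dict(zip(ids, feats))
        dec = det_tradeoff(fit, cycle, pair=(by_id[id1], by_id[id2]))
        rows.append(
            {
                "cycle_id": cycle.cycle_id,
                "embryo_1": id1,
                "embryo_2": id2,
                "set_p1": dec.set_p1,
                "set_p2": dec.set_p2,
                "det_p0": dec.det_p0,
                "det_singleton": dec.det_singleton,
                "det_twin": dec.det_twin,
                "singleton_gain": dec.singleton_gain,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cycle_id",
            "embryo_1",
            "embryo_2",
            "set_p1",
            "set_p2",
            "det_p0",
            "det_singleton",
            "det_twin",
            "singleton_gain",
        ],
    )
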