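"""Event vocabulary, cost schemes and model variants.

The reconciliation score of an annotated history is the weighted event sum

    pi = delta * n_D + tau * n_T + lambda * n_L

where duplications cost ``delta``, transfers ``tau`` and losses ``lambda``;
speciations (co-divergence at a binary species node) and deep coalescences
(co-divergence at a species polytomy) are free. The four model variants
differ on two axes: whether species polytomies / coalescence events are
admitted (the "I" in DTI/DTLI) and whether the loss term participates in
the optimization criterion (the "L" in DTL/DTLI). Models without "L" still
reconstruct and report losses post hoc; they simply do not score them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

__all__ = [
    "DUPLICATION", "TRANSFER", "SPECIATION", "COALESCENCE",
    "CODIV", "EMIT", "LEAF",
    "MODELS", "CostScheme", "LossRecord", "model_allows_ils",
    "model_scores_losses", "effective_costs",
]

# Event labels for internal gene nodes. Losses are edge annotations, not
# node events.
DUPLICATION = "D"
TRANSFER = "T"
SPECIATION = "S"
COALESCENCE = "C"

# How a gene node consumes its species assignment; the parent edge's loss
# count depends on this. A co-divergence (speciation/coalescence) divides
# the lineage along the species divergence it sits on; duplications and
# transfers re-emit copies from within the species branch.
CODIV = 0
EMIT = 1
LEAF = 2

MODELS = ("DT", "DTI", "DTL", "DTLI")


@dataclass(frozen=True)
class CostScheme:
    """Event weights. ``dup``/``loss`` default to the standard empirical
    setting (3 and 2); ``trans`` has no default and must be supplied
    (``math.inf`` disables transfers entirely). ``losses_in_score`` is
    normally derived from the model variant via :func:`effective_costs`."""

    trans: float
    dup: float = 3.0
    loss: float = 2.0
    losses_in_score: bool = True

    def __post_init__(self):
        for name in ("dup", "loss", "trans"):
            v = getattr(self, name)
            if math.isnan(v) or v < 0:
                raise ValueError(f"{name} cost must be >= 0, got {v}")

    def kappa(self, event: str) -> float:
        """The node cost of an event; co-divergences are free."""
        if event == DUPLICATION:
            return self.dup
        if event == TRANSFER:
            return self.trans
        return 0.0


def model_allows_ils(model: str) -> bool:
    _check_model(model)
    return model in ("DTI", "DTLI")


def model_scores_losses(model: str) -> bool:
    _check_model(model)
    return model in ("DTL", "DTLI")


def _check_model(model: str) -> None:
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def effective_costs(costs: CostScheme, model: str) -> CostScheme:
    """The cost scheme with ``losses_in_score`` set by the model variant."""
    return replace(costs, losses_in_score=model_scores_losses(model))


class LossRecord(NamedTuple):
    """A loss on a gene-tree edge: the species node whose divergence the
    surviving lineage crossed (or terminated in) and the child lineages of
    that node in which the gene did not survive. At a binary species node
    ``lost`` is the single bypassed sibling; at a polytomy it is the whole
    uncovered child set, lost as one unit (any uncovered subset is a clade
    in some binary resolution of the polytomy)."""

    species: int
    lost: tuple[int, ...]
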