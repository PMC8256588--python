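"""Two-state discrete-time Markov chain over eosinophilia calls.

The sensitivity analysis for the extrapolated prevalence: each sample
classification (eosinophilic E / non-eosinophilic N) is a chain state, and
transition probabilities are estimated by maximum likelihood from pooled
consecutive within-patient examination pairs.  Time is the examination
index — unequal calendar intervals between examinations are ignored, as
the model is explicitly discrete-time.

For a two-state chain with transition probabilities ``p_NE`` (N -> E) and
``p_EN`` (E -> N), the stationary distribution is available in closed
form: ``pi_E = p_NE / (p_NE + p_EN)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .cohort import ValidationError

__all__ = ["TransitionModel", "estimate_transitions", "chain_prevalence"]


@dataclass(frozen=True)
class TransitionModel:
    """MLE of a two-state chain from pooled consecutive-pair counts."""

    threshold_name: str
    n_nn: int
    n_ne: int
    n_en: int
    n_ee: int
    smoothing: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_nn, self.n_ne, self.n_en, self.n_ee) < 0:
            raise ValidationError("transition counts must be non-negative")
        if self.smoothing < 0:
            raise ValidationError("smoothing must be non-negative")

    @property
    def _row_n(self) -> float:
        return self.n_nn + self.n_ne + 2 * self.smoothing

    @property
    def _row_e(self) -> float:
        return self.n_en + self.n_ee + 2 * self.smoothing

    @property
    def row_n_defined(self) -> bool:
        return self._row_n > 0

    @property
    def row_e_defined(self) -> bool:
        return self._row_e > 0

    @property
    def p_ne(self) -> Optional[float]:
        if not self.row_n_defined:
            return None
        return (self.n_ne + self.smoothing) / self._row_n

    @property
    def p_nn(self) -> Optional[float]:
        return None if self.p_ne is None else 1.0 - self.p_ne

    @property
    def p_en(self) -> Optional[float]:
        if not self.row_e_defined:
            return None
        return (self.n_en + self.smoothing) / self._row_e

    @property
    def p_ee(self) -> Optional[float]:
        return None if self.p_en is None else 1.0 - self.p_en

    @property
    def fully_defined(self) -> bool:
        return self.row_n_defined and self.row_e_defined

    @property
    def stationary(self) -> Optional[tuple[float, float]]:
        """(pi_N, pi_E); None when either row is undefined or the chain is
        absorbing-degenerate (p_NE = p_EN = 0)."""
        if not self.fully_defined:
            return None
        denom = self.p_ne + self.p_en
        if denom == 0:
            return None
        pi_e = self.p_ne / denom
        return (1.0 - pi_e, pi_e)

    def to_dict(self) -> dict:
        return {
            "threshold_name": self.threshold_name,
            "counts": {
                "n_nn": self.n_nn,
                "n_ne": self.n_ne,
                "n_en": self.n_en,
                "n_ee": self.n_ee,
            },
            "p_ne": self.p_ne,
            "p_nn": self.p_nn,
            "p_en": self.p_en,
            "p_ee": self.p_ee,
            "stationary": self.stationary,
            "smoothing": self.smoothing,
        }


def estimate_transitions(
    call_sequences: Iterable[Sequence[bool]],
    threshold_name: str = "",
    smoothing: float = 0.0,
) -> TransitionModel:
    """Estimate the chain from per-patient ordered call sequences.

    Each sequence is an ordered list of booleans (True = eosinophilic);
    indeterminate calls must be excluded upstream.  Consecutive-pair
    transition counts are pooled across patients (one chain for the
    cohort) and row-normalized — the MLE.  ``smoothing`` adds the given
    pseudo-count to every cell (off by default; +1 useful on sparse
    synthetic runs).
    """
    n = [[0, 0], [0, 0]]
    any_pair = False
    for seq in call_sequences:
        for a, b in zip(seq, seq[1:]):
            n[int(bool(a))][int(bool(b))] += 1
            any_pair = True
    if not any_pair and smoothing == 0:
        raise ValidationError("no consecutive pairs: chain not estimable")
    return TransitionModel(
        threshold_name=threshold_name,
        n_nn=n[0][0],
        n_ne=n[0][1],
        n_en=n[1][0],
        n_ee=n[1][1],
        smoothing=smoothing,
    )


def chain_prevalence(
    model: TransitionModel,
    horizon: str = "stationary",
    current_prev: Optional[float] = None,
) -> float:
    """Prevalence implied by the fitted chain.

    ``horizon="stationary"`` returns the long-run eosinophilic occupancy
    ``pi_E``.  ``horizon="next_step"`` returns the composite
    ``current_prev + (1 - current_prev) * p_NE`` — the share eosinophilic
    now or at the next examination — and requires ``current_prev``.
    """
    if not model.fully_defined:
        raise ValidationError("chain rows undefined; cannot project")
    if horizon == "stationary":
        st = model.stationary
        if st is None:
            raise ValidationError("stationary distribution undefined")
        return st[1]
    if horizon == "next_step":
        if current_prev is None or not (0.0 <= current_prev <= 1.0):
            raise ValidationError(
                "next_step horizon requires current_prev in [0, 1]"
            )
        return current_prev + (1.0 - current_prev) * model.p_ne
    raise ValidationError(f"unknown horizon {horizon!r}")
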