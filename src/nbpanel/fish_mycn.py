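"""MYCN amplification scoring from FISH signal counts.

MYCN is not on the sequencing panel; amplification status enters the
analysis exclusively through FISH. The call is a single binary: the summed
MYCN/CEP2 signal ratio across nuclei reaching the fold threshold
(default 10, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class FishScoringError(RuntimeError):
    """Hybridization failure (no reference signals)."""


@dataclass(frozen=True)
class FishCount:
    """Per-nucleus MYCN and CEP2 (reference) signal counts for one sample."""

    sample_id: str
    mycn_signals: np.ndarray
    cep2_signals: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mycn_signals, dtype=int)
        c = np.asarray(self.cep2_signals, dtype=int)
        if m.shape != c.shape:
            raise ValueError("MYCN and CEP2 count vectors differ in length")
        if (m < 0).any() or (c < 0).any():
            raise ValueError("signal counts must be non-negative")
        object.__setattr__(self, "mycn_signals", m)
        object.__setattr__(self, "cep2_signals", c)

    @property
    def n_nuclei(self) -> int:
        return len(self.mycn_signals)


def score_mycn(counts: FishCount, fold_threshold: float = 10.0) -> tuple[float, bool]:
    """(ratio, amplified) from summed signals across nuclei.

    The ratio is total MYCN signals over total CEP2 signals — summing first
    avoids division by zero in CEP2-null nuclei. Amplified means ratio >=
    ``fold_threshold`` (boundary inclusive).
    """
    total_cep2 = int(counts.cep2_signals.sum())
    if total_cep2 == 0:
        raise FishScoringError(
            f"sample {counts.sample_id}: no CEP2 signals (hybridization failure)"
        )
    ratio = float(counts.mycn_signals.sum()) / total_cep2
    return ratio, ratio >= fold_threshold
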