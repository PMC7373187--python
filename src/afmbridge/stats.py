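"""Condition-level aggregation of per-image junction measurements.

Mirrors the headline comparisons of DNA-bridging AFM experiments: the
fraction of observed molecules carrying a junction, the mean ± SEM of
junction height differences per condition, unpaired equal-variance
Student's t tests between conditions, and fold changes of inter-/intra-
molecular junction percentages between deposition densities.

An intermolecular component contains two molecules, so it contributes two
to the molecule total and two junction-carrying molecules; intra and
ambiguous components contribute one. SEM uses the n−1 sample standard
deviation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SampleSummary",
    "TTestResult",
    "summarize_sample",
    "unpaired_t_test",
    "density_fold_change",
]

logger = logging.getLogger(__name__)


@dataclass
class SampleSummary:
    """Per-condition statistics over a set of traced images."""

    condition: str
    density_class: str
    n_molecules: int
    n_junctions: int
    n_intra: int
    n_inter: int
    n_ambiguous: int
    pct_molecules_with_junction: float
    pct_intra: float  # % of molecules displaying an intramolecular association
    pct_inter: float  # % of molecules displaying an intermolecular association
    mean_height_diff: float | None
    sem_height_diff: float | None

    def __post_init__(self) -> None:
        for p in (self.pct_molecules_with_junction, self.pct_intra, self.pct_inter):
            if not (0.0 <= p <= 100.0):
                raise ValueError(f"percentage out of [0, 100]: {p}")


def _molecules_per_component(jtype: str) -> int:
    return 2 if jtype == "inter" else 1


def summarize_sample(
    molecules: pd.DataFrame,
    junctions: pd.DataFrame,
    condition: str = "",
    density_class: str = "",
) -> SampleSummary:
    """Aggregate trace output (possibly concatenated over images) into one
    summary row.

    ``molecules`` / ``junctions`` are the frames produced by
    :func:`afmbridge.trace.analyze_image`. Height statistics are reported
    as None when no junction height was measurable. Summaries are additive:
    summarizing the concatenation of two halves equals merging their counts
    and recomputing the pooled mean/SEM.
    """
    if len(molecules) == 0:
        raise ValueError("summarize_sample requires at least one molecule")
    jtypes = molecules["jtype"].fillna("ambiguous")
    mol_counts = jtypes.map(_molecules_per_component)
    n_molecules = int(mol_counts.sum())

    has_junction = molecules["n_junctions"] > 0
    n_with = int(mol_counts[has_junction].sum())
    n_intra_mol = int(mol_counts[has_junction & (jtypes == "intra")].sum())
    n_inter_mol = int(mol_counts[has_junction & (jtypes == "inter")].sum())

    if len(junctions):
        type_counts = junctions["type"].value_counts()
        n_intra = int(type_counts.get("intra", 0))
        n_inter = int(type_counts.get("inter", 0))
        n_amb = int(len(junctions) - n_intra - n_inter)
        diffs = junctions["height_diff_nm"].dropna().to_numpy()
    else:
        n_intra = n_inter = n_amb = 0
        diffs = np.empty(0)

    if len(diffs) >= 1:
        mean = float(np.mean(diffs))
        sem = float(np.std(diffs, ddof=1) / math.sqrt(len(diffs))) if len(diffs) > 1 else None
    else:
        mean = sem = None

    return SampleSummary(
        condition=condition,
        density_class=density_class,
        n_molecules=n_molecules,
        n_junctions=int(len(junctions)),
        n_intra=n_intra,
        n_inter=n_inter,
        n_ambiguous=n_amb,
        pct_molecules_with_junction=100.0 * n_with / n_molecules,
        pct_intra=100.0 * n_intra_mol / n_molecules,
        pct_inter=100.0 * n_inter_mol / n_molecules,
        mean_height_diff=mean,
        sem_height_diff=sem,
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def unpaired_t_test(a, b) -> TTestResult:
    """Unpaired equal-variance Student's t test, two-sided.

    t = (x̄_a − x̄_b) / (s_p √(1/n_a + 1/n_b)), df = n_a + n_b − 2, with
    s_p² the pooled variance. Degenerate zero-variance inputs: equal means
    give (t=0, p=1); unequal means give p→0 and are flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = len(a), len(b)
    df = na + nb - 2
    pooled = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / df
    delta = float(np.mean(a) - np.mean(b))
    if pooled == 0.0:
        if delta == 0.0:
            return TTestResult(0.0, df, 1.0)
        logger.warning("zero pooled variance with unequal means: p -> 0")
        return TTestResult(math.copysign(math.inf, delta), df, 0.0, degenerate=True)
    t = delta / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(float(t), df, p)


def density_fold_change(
    summary_low: SampleSummary, summary_high: SampleSummary
) -> tuple[float, float]:
    """Density effect on junction character.

    Returns (fold_inter, fold_intra): the ratio of intermolecular
    percentages high/low (crowding promotes molecule–molecule bridging)
    and of intramolecular percentages low/high (self-association is
    relatively suppressed at high density). Zero denominators are reported
    as inf and flagged.
    """
    if summary_low.n_molecules == 0 or summary_high.n_molecules == 0:
        raise ValueError("both summaries need molecule counts > 0")

    def ratio(num: float, den: float, label: str) -> float:
        if den == 0.0:
            logger.warning("%s: zero denominator, fold change reported as inf", label)
            return math.inf
        return num / den

    fold_inter = ratio(summary_high.pct_inter, summary_low.pct_inter, "fold_inter")
    fold_intra = ratio(summary_low.pct_intra, summary_high.pct_intra, "fold_intra")
    return fold_inter, fold_intra
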