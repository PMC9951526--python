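"""Sequencing-library QC: balance, inequality, and error-content statistics.

Works on variant-caller style count tables (one genotype string plus a
read count per row, as produced by saturation-mutagenesis callers).
Designed variants are recognized by their exact nucleotide-level
signature; everything else is classified into off-target error classes
(deletions and insertions by length bin, synonymous and missense point
errors, multi-error reads). Balance statistics follow the conventions
used to evaluate oligo-pool libraries: per-position coverage and
per-sublibrary median fold-range, Lorenz curves with Gini coefficients
(0 = perfectly even representation), and Welch t-tests between variant
kinds with Benjamini-Hochberg control for multiple comparisons.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .design_core import Design
from .sequence_model import CODON_TO_AA

__all__ = [
    "CountTable",
    "QCReport",
    "DEFAULT_LENGTH_BINS",
    "tabulate_counts",
    "positional_coverage",
    "lorenz_gini",
    "type_bias_tests",
    "qc_report",
]

#: inclusive nt-length bins for off-target indels; None = unbounded
DEFAULT_LENGTH_BINS: tuple[tuple[int, int | None], ...] = ((1, 1), (2, 3), (4, 30), (31, None))

_OP_POINT = re.compile(r"^(\d+)([ACGT])>([ACGT])$")
_OP_DEL = re.compile(r"^(\d+)_(\d+)del$")
_OP_INS = re.compile(r"^(\d+)_(\d+)ins([ACGT]+)$")


@dataclass
class CountTable:
    """Classified per-variant read counts.

    ``df`` has one row per distinct genotype with columns ``variant``
    (designed name or the genotype string), ``genotype``, ``count``,
    ``designed`` (bool), ``kind``, ``position``, ``sublibrary`` (designed
    rows only) and ``offtarget_class`` (off-target rows only).
    ``malformed`` lists genotype strings that could not be parsed.
    """

    df: pd.DataFrame
    malformed: list[str] = field(default_factory=list)

    @property
    def designed(self) -> pd.DataFrame:
        return self.df[self.df["designed"]]

    @property
    def offtarget(self) -> pd.DataFrame:
        return self.df[~self.df["designed"]]

    @property
    def designed_read_fraction(self) -> float:
        total = self.df["count"].sum()
        return float(self.designed["count"].sum() / total) if total else 0.0

    def offtarget_class_counts(self) -> pd.Series:
        return self.offtarget.groupby("offtarget_class")["count"].sum()


def _bin_label(prefix: str, length: int, bins: Sequence[tuple[int, int | None]]) -> str:
    for lo, hi in bins:
        if length >= lo and (hi is None or length <= hi):
            if hi is None:
                return f"{prefix}_gt{lo - 1}"
            return f"{prefix}_{lo}" if lo == hi else f"{prefix}_{lo}_{hi}"
    return f"{prefix}_other"


def _classify_offtarget(
    genotype: str, cds: str, bins: Sequence[tuple[int, int | None]]
) -> str | None:
    """Error class for a non-designed genotype; None when unparseable."""
    ops = genotype.split(";")
    parsed = []
    for op in ops:
        m = _OP_DEL.match(op) or _OP_INS.match(op) or _OP_POINT.match(op)
        if m is None:
            return None
        parsed.append((op, m))
    if len(parsed) > 1:
        return "multiple"
    op, m = parsed[0]
    if _OP_DEL.match(op):
        start, end = int(m.group(1)), int(m.group(2))
        return _bin_label("del", end - start + 1, bins)
    if _OP_INS.match(op):
        return _bin_label("ins", len(m.group(3)), bins)
    pos, old, new = int(m.group(1)), m.group(2), m.group(3)
    if not (1 <= pos <= len(cds)) or cds[pos - 1] != old:
        return "other"
    ci = (pos - 1) // 3
    codon = cds[3 * ci : 3 * ci + 3]
    j = (pos - 1) % 3
    mutated = codon[:j] + new + codon[j + 1 :]
    return "synonymous_point" if CODON_TO_AA[mutated] == CODON_TO_AA[codon] else "missense_point"


def tabulate_counts(
    counts: pd.DataFrame | str | Path,
    design: Design,
    length_bins: Sequence[tuple[int, int | None]] = DEFAULT_LENGTH_BINS,
) -> CountTable:
    """Match called genotypes to the design and classify the remainder.

    ``counts`` is a DataFrame or CSV with ``genotype`` and ``count``
    columns. Each record either matches a designed variant's exact
    nucleotide signature or is placed into an off-target error class.
    Malformed genotype strings are reported on the returned table, never
    fatal.
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.read_csv(counts)
    sig_to_name = {o.signature: name for name, o in design.oligos.items()}
    kinds = {v.name: v for v in design.variants}
    rows = []
    malformed: list[str] = []
    for genotype, count in zip(counts["genotype"], counts["count"]):
        genotype = str(genotype)
        count = int(count)
        if count < 0:
            raise ValueError(f"negative count for genotype {genotype!r}")
        name = sig_to_name.get(genotype)
        if name is not None:
            v = kinds[name]
            rows.append(
                {
                    "variant": name,
                    "genotype": genotype,
                    "count": count,
                    "designed": True,
                    "kind": v.kind,
                    "position": v.codon_pos,
                    "sublibrary": design.oligos[name].sublibrary,
                    "offtarget_class": None,
                }
            )
            continue
        cls = _classify_offtarget(genotype, design.gene.cds, length_bins)
        if cls is None:
            malformed.append(genotype)
            continue
        rows.append(
            {
                "variant": genotype,
                "genotype": genotype,
                "count": count,
                "designed": False,
                "kind": None,
                "position": None,
                "sublibrary": None,
                "offtarget_class": cls,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "variant",
            "genotype",
            "count",
            "designed",
            "kind",
            "position",
            "sublibrary",
            "offtarget_class",
        ],
    )
    return CountTable(df=df, malformed=malformed)


def positional_coverage(
    tab: CountTable, design: Design | None = None
) -> tuple[pd.Series, pd.Series, float]:
    """Per-position totals, per-sublibrary medians, and median fold-range.

    The fold-range is ``max(median) / min(median)`` across sublibraries
    (infinite, with a warning, when some sublibrary median is zero);
    libraries within 2-fold are conventionally considered well balanced.
    """
    des = tab.designed
    if des.empty:
        raise ValueError("no designed variants in the count table")
    per_pos = des.groupby("position")["count"].sum().sort_index()
    pos_sub = des.groupby(["sublibrary", "position"])["count"].sum()
    medians = pos_sub.groupby(level="sublibrary").median().sort_index()
    if (medians == 0).any():
        warnings.warn("sublibrary with zero median coverage; fold-range is infinite")
        fold = float("inf")
    else:
        fold = float(medians.max() / medians.min())
    return per_pos, medians, fold


def lorenz_gini(counts) -> tuple[np.ndarray, float]:
    """Lorenz curve points and Gini coefficient of a count vector.

    Counts are sorted ascending; the curve gives the cumulative share of
    reads against the cumulative share of variants, and ``Gini = 1 - 2 *
    area`` under it (trapezoidal). A perfectly even library lies on the
    diagonal with Gini 0. Scale-invariant; all-zero input is an error.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    c = np.sort(c)
    n = c.size
    x = np.arange(n + 1) / n
    y = np.concatenate([[0.0], np.cumsum(c) / total])
    area = float(np.trapezoid(y, x))
    return np.column_stack([x, y]), 1.0 - 2.0 * area


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def type_bias_tests(
    tab: CountTable, method: str = "fdr_bh"
) -> pd.DataFrame:
    """Pairwise Welch t-tests of per-position incorporation between kinds.

    For each variant kind, the per-position mean read frequency (counts
    normalized to the designed total) forms one observation per position;
    every pair of kinds is compared with a two-sided Welch t-test and the
    p-values are adjusted (Benjamini-Hochberg by default, ``method`` is
    any statsmodels multipletests method such as ``"bonferroni"``).
    Returns a table with statistic, raw p, adjusted p, and significance
    stars (* <0.05, ** <0.01, *** <0.001).
    """
    des = tab.designed
    total = des["count"].sum()
    if total == 0:
        raise ValueError("no designed reads")
    freq = des.assign(freq=des["count"] / total)
    per = freq.groupby(["kind", "position"])["freq"].mean()
    vectors: dict[str, np.ndarray] = {}
    for kind in per.index.get_level_values("kind").unique():
        vec = per.loc[kind].to_numpy()
        if vec.size < 2:
            warnings.warn(f"kind {kind!r} has fewer than 2 positions; skipped")
            continue
        vectors[kind] = vec
    kinds = sorted(vectors)
    if len(kinds) < 2:
        raise ValueError("need at least two variant kinds with >=2 positions")
    rows = []
    for i, a in enumerate(kinds):
        for b in kinds[i + 1 :]:
            t, p = sps.ttest_ind(vectors[a], vectors[b], equal_var=False)
            rows.append({"kind_a": a, "kind_b": b, "statistic": float(t), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method=method)[1]
    out["significance"] = out["p_adj"].map(_stars)
    return out


@dataclass
class QCReport:
    """Aggregate library-QC summary (JSON-serializable via ``to_dict``)."""

    per_position: pd.Series
    sublibrary_medians: pd.Series
    fold_range: float
    gini: float
    designed_fraction: float
    offtarget_classes: dict[str, int]
    tests: pd.DataFrame
    malformed: list[str]

    def to_dict(self) -> dict:
        return {
            "designed_read_fraction": self.designed_fraction,
            "gini": self.gini,
            "sublibrary_median_fold_range": self.fold_range,
            "sublibrary_medians": {int(k): float(v) for k, v in self.sublibrary_medians.items()},
            "offtarget_class_read_counts": self.offtarget_classes,
            "type_bias_tests": self.tests.to_dict(orient="records"),
            "n_malformed_genotypes": len(self.malformed),
        }


def qc_report(tab: CountTable, design: Design) -> QCReport:
    """Run the full QC battery on one classified count table."""
    per_pos, medians, fold = positional_coverage(tab, design)
    _, gini = lorenz_gini(tab.designed["count"].to_numpy())
    try:
        tests = type_bias_tests(tab)
    except ValueError:
        tests = pd.DataFrame(columns=["kind_a", "kind_b", "statistic", "p_raw", "p_adj", "significance"])
    return QCReport(
        per_position=per_pos,
        sublibrary_medians=medians,
        fold_range=fold,
        gini=float(gini),
        designed_fraction=tab.designed_read_fraction,
        offtarget_classes={str(k): int(v) for k, v in tab.offtarget_class_counts().items()},
        tests=tests,
        malformed=tab.malformed,
    )
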