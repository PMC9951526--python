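"""Fitness-score analyses for indel-containing mutational scans.

Consumes per-variant enrichment score tables (Enrich2-style: an HGVS-like
identifier, a score, a standard error, optional per-replicate columns) and
implements the downstream comparisons used to interpret indel scans:

* per-kind score distributions (the deletion < insertion < missense <
  synonymous disruption hierarchy) and per-position means by indel length;
* Pearson correlation between inserting a Gly and substituting to Gly at
  the same position — separating the effect of added length from changed
  physical chemistry;
* Wilcoxon rank-sum comparisons across secondary-structure strata
  (structured vs unstructured, helix vs sheet);
* association between experimentally tolerated indel positions and
  evolutionarily observed indel positions, read off a profile HMM's
  match->insert / match->delete transition probabilities and tested with
  Fisher's exact test on a 2x2 table.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyhmmer
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats as sps

__all__ = [
    "ScoreTable",
    "StructureAnnotation",
    "HMMIndelProfile",
    "parse_variant_name",
    "read_scores",
    "class_summaries",
    "gly_correlation",
    "wilcoxon_rank_sum",
    "fisher_exact_two_sided",
    "structure_strata",
    "read_hmm_indel_profile",
    "indel_conservation_test",
]

_RE_INS = re.compile(r"^p\.([A-Z*])(\d+)_ins([A-Z]+)$")
_RE_DEL = re.compile(r"^p\.([A-Z])(\d+)(?:_([A-Z])(\d+))?del$")
_RE_SYN = re.compile(r"^p\.([A-Z])(\d+)=$")
_RE_MIS = re.compile(r"^p\.([A-Z])(\d+)([A-Z*])$")


def parse_variant_name(name: str) -> tuple[str, int, str, int]:
    """Parse an HGVS-like variant name.

    Returns ``(kind, position, payload, length)`` where ``payload`` is the
    inserted amino acid string (insertions) or target amino acid
    (missense/stop) and ``length`` is the indel length in residues (0 for
    point variants). Raises ``ValueError`` for unrecognized names.
    """
    m = _RE_INS.match(name)
    if m:
        return "insertion", int(m.group(2)), m.group(3), len(m.group(3))
    m = _RE_DEL.match(name)
    if m:
        start = int(m.group(2))
        end = int(m.group(4)) if m.group(4) else start
        return "deletion", start, "", end - start + 1
    m = _RE_SYN.match(name)
    if m:
        return "synonymous", int(m.group(2)), "", 0
    m = _RE_MIS.match(name)
    if m:
        kind = "stop" if m.group(3) == "*" else "missense"
        return kind, int(m.group(2)), m.group(3), 0
    raise ValueError(f"unrecognized variant name {name!r}")


@dataclass
class ScoreTable:
    """Per-variant fitness scores with parsed variant metadata.

    ``df`` columns: ``name, kind, position, payload, length, score, se``
    plus any ``score_rep*`` replicate columns. ``skipped`` lists
    identifiers that could not be parsed.
    """

    df: pd.DataFrame
    skipped: list[str] = field(default_factory=list)

    @property
    def replicate_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("score_rep")]

    def complete_replicates(self) -> "ScoreTable":
        """Rows scored in every replicate (no-op without replicate columns)."""
        reps = self.replicate_columns
        if not reps:
            return self
        return ScoreTable(self.df.dropna(subset=reps).reset_index(drop=True), self.skipped)

    def subset(self, kinds: Iterable[str]) -> pd.DataFrame:
        kinds = set(kinds)
        return self.df[self.df["kind"].isin(kinds)]


def read_scores(source: str | Path | pd.DataFrame) -> ScoreTable:
    """Load an Enrich2-style score table (TSV/CSV or DataFrame).

    The identifier column is ``hgvs``/``variant``/``name``/``id`` (or the
    first column); scores come from ``score`` and standard errors from
    ``SE``/``se``/``stderr`` when present. Unparseable identifiers are
    excluded and reported on the result; a duplicate identifier or a table
    with no parseable rows is an error.
    """
    if isinstance(source, pd.DataFrame):
        raw = source.copy()
    else:
        path = Path(source)
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        raw = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in raw.columns}
    id_col = next((cols[k] for k in ("hgvs", "variant", "name", "id") if k in cols), raw.columns[0])
    if "score" not in cols:
        raise ValueError("score column not found")
    se_col = next((cols[k] for k in ("se", "stderr", "standard_error") if k in cols), None)
    dup = raw[id_col][raw[id_col].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate identifier {dup.iloc[0]!r}")
    rows = []
    skipped: list[str] = []
    rep_cols = [c for c in raw.columns if c.lower().startswith("score_rep")]
    for _, rec in raw.iterrows():
        name = str(rec[id_col])
        try:
            kind, pos, payload, length = parse_variant_name(name)
        except ValueError:
            skipped.append(name)
            continue
        row = {
            "name": name,
            "kind": kind,
            "position": pos,
            "payload": payload,
            "length": length,
            "score": float(rec[cols["score"]]),
            "se": float(rec[se_col]) if se_col is not None else np.nan,
        }
        for rc in rep_cols:
            row[f"score_rep{rep_cols.index(rc) + 1}"] = float(rec[rc])
        rows.append(row)
    if not rows:
        raise ValueError("no parseable score rows")
    return ScoreTable(pd.DataFrame(rows), skipped)


# ---------------------------------------------------------------------------
# Class summaries and Gly correlation
# ---------------------------------------------------------------------------


def class_summaries(st: ScoreTable) -> dict[str, pd.DataFrame]:
    """Distribution statistics per variant kind and per-position indel means.

    ``by_kind``: mean/median/std/count of finite scores per kind.
    ``per_position``: per-position mean score for insertions and deletions
    of each length (columns are ``(kind, length)``), the per-residue indel
    tolerance track.
    """
    df = st.df[np.isfinite(st.df["score"])]
    if df.empty:
        raise ValueError("no finite scores")
    by_kind = (
        df.groupby("kind")["score"].agg(["mean", "median", "std", "count"]).sort_index()
    )
    indels = df[df["kind"].isin(["insertion", "deletion"])]
    per_position = (
        indels.pivot_table(index="position", columns=["kind", "length"], values="score", aggfunc="mean")
        if not indels.empty
        else pd.DataFrame()
    )
    return {"by_kind": by_kind, "per_position": per_position}


def gly_correlation(
    st: ScoreTable, complete_replicates_only: bool = False
) -> tuple[int, float, float]:
    """Pearson correlation of single-Gly insertion vs X->Gly substitution.

    Pairs every position that has both a 1-residue Gly insertion score and
    a missense-to-Gly score; returns ``(n positions, r, p)``. Fewer than
    three complete pairs is an error.
    """
    if complete_replicates_only:
        st = st.complete_replicates()
    df = st.df[np.isfinite(st.df["score"])]
    ins = df[(df["kind"] == "insertion") & (df["payload"] == "G")].set_index("position")["score"]
    sub = df[(df["kind"] == "missense") & (df["payload"] == "G")].set_index("position")["score"]
    ins = ins[~ins.index.duplicated()]
    sub = sub[~sub.index.duplicated()]
    common = ins.index.intersection(sub.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} positions with both Gly-ins and Gly-sub scores")
    r, p = sps.pearsonr(ins.loc[common], sub.loc[common])
    return len(common), float(r), float(p)


# ---------------------------------------------------------------------------
# Secondary-structure strata
# ---------------------------------------------------------------------------

_STRUCTURE_CLASSES = {"helix", "sheet", "loop", "unstructured"}


@dataclass(frozen=True)
class StructureAnnotation:
    """Per-position secondary-structure class.

    ``classes[i]`` annotates residue ``i+1`` with one of ``helix``,
    ``sheet``, ``loop``, ``unstructured``. Positions in any class other
    than ``unstructured`` count as structured.
    """

    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.classes) - _STRUCTURE_CLASSES
        if bad:
            raise ValueError(f"unknown structure classes: {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StructureAnnotation":
        """Two-column TSV: 1-based position, class; positions must be 1..L."""
        rows: dict[int, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pos, klass = line.split("\t")
            rows[int(pos)] = klass
        if sorted(rows) != list(range(1, len(rows) + 1)):
            raise ValueError("annotation positions must be contiguous from 1")
        return cls(tuple(rows[i] for i in sorted(rows)))

    def klass(self, position: int) -> str:
        return self.classes[position - 1]

    def structured(self, position: int) -> bool:
        return self.klass(position) != "unstructured"


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both samples have at most 50
    observations and there are no ties, otherwise the tie-corrected normal
    approximation. Degenerate pooled data (every value identical across
    both samples, so the rank variance vanishes) gives p = 1. Returns
    ``(U statistic, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return x.size * y.size / 2.0, 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and max(x.size, y.size) <= 50) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):  # fully tied ranks under the tie-corrected normal
        p = 1.0
    return float(res.statistic), min(p, 1.0)


def structure_strata(
    st: ScoreTable,
    ann: StructureAnnotation,
    kind_subsets: Sequence[tuple[str, tuple[str, ...]]] = (
        ("all", ("missense", "synonymous", "insertion", "deletion", "stop")),
        ("missense", ("missense",)),
        ("insertion", ("insertion",)),
        ("deletion", ("deletion",)),
        ("indel", ("insertion", "deletion")),
    ),
) -> pd.DataFrame:
    """Stratified score comparisons with Wilcoxon rank-sum statistics.

    For each variant-kind subset, compares structured vs unstructured
    positions and helix vs sheet positions. Strata with fewer than two
    values are skipped with a warning. Returns one row per comparison with
    sample sizes, medians, U, and the two-sided p-value.
    """
    df = st.df[np.isfinite(st.df["score"])]
    n_ann = len(ann.classes)
    df = df[(df["position"] >= 1) & (df["position"] <= n_ann)]
    klass = df["position"].map(lambda p: ann.klass(int(p)))
    structured = klass != "unstructured"
    comparisons = [
        ("structured_vs_unstructured", structured, ~structured),
        ("helix_vs_sheet", klass == "helix", klass == "sheet"),
    ]
    rows = []
    for subset_name, kinds in kind_subsets:
        sub = df["kind"].isin(set(kinds))
        for comp_name, mask_a, mask_b in comparisons:
            a = df.loc[sub & mask_a, "score"].to_numpy()
            b = df.loc[sub & mask_b, "score"].to_numpy()
            if a.size < 2 or b.size < 2:
                warnings.warn(f"{comp_name} [{subset_name}]: stratum with <2 values; skipped")
                continue
            u, p = wilcoxon_rank_sum(a, b)
            rows.append(
                {
                    "comparison": comp_name,
                    "kinds": subset_name,
                    "n_a": a.size,
                    "n_b": b.size,
                    "median_a": float(np.median(a)),
                    "median_b": float(np.median(b)),
                    "U": u,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Two-sidedness follows the minimum-likelihood rule: the p-value sums
    the hypergeometric probabilities of every table (with the observed
    margins) no more probable than the observed one.
    """
    _odds, p = sps.fisher_exact(np.asarray(table, dtype=int), alternative="two-sided")
    return float(p)


# ---------------------------------------------------------------------------
# Profile-HMM indel conservation
# ---------------------------------------------------------------------------


@dataclass
class HMMIndelProfile:
    """Per-target-position evolutionary indel probabilities.

    ``ins_prob[pos]`` / ``del_prob[pos]`` hold the profile's
    match->insert / match->delete transition probabilities for the match
    state mapped onto 1-based target position ``pos`` (mapping by local
    alignment of the profile consensus to the target protein; injective
    on mapped positions).
    """

    ins_prob: dict[int, float]
    del_prob: dict[int, float]
    sources: list[str] = field(default_factory=list)

    @property
    def positions(self) -> list[int]:
        return sorted(self.ins_prob)


def _text_transitions(path: str | Path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Full-precision m->i / m->d probabilities per profile in a HMMER3 file.

    The profile reader keeps probabilities in single precision; for the
    transition probabilities themselves we decode the file's negative-log
    values in double precision. One ``(m2i, m2d)`` pair per profile, in
    file order.
    """

    def dec(tok: str) -> float:
        return 0.0 if tok == "*" else float(np.exp(-float(tok)))

    out: list[tuple[np.ndarray, np.ndarray]] = []
    for block in Path(path).read_text().split("\n//"):
        if "HMM " not in block:
            continue
        lines = block.splitlines()
        mi: list[float] = []
        md: list[float] = []
        for i, line in enumerate(lines):
            tok = line.split()
            if tok and tok[0].isdigit() and i + 2 < len(lines):
                trans = lines[i + 2].split()
                if len(trans) == 7:
                    mi.append(dec(trans[1]))
                    md.append(dec(trans[2]))
        out.append((np.asarray(mi), np.asarray(md)))
    return out


def _consensus_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


def read_hmm_indel_profile(
    hmm_paths: str | Path | Sequence[str | Path],
    target_protein: str,
) -> HMMIndelProfile:
    """Extract match->insert/delete probabilities and map them to a target.

    Reads one or more HMMER3 profiles, takes each match state's m->i and
    m->d transition probability (the file stores negative natural logs;
    decoding is handled by the profile reader), and maps match states to
    1-based positions of ``target_protein`` by locally aligning the
    profile consensus to the target. Mapped coverage below 50% of the
    profile's match states triggers a warning. Later profiles never
    overwrite positions mapped by earlier ones.
    """
    if isinstance(hmm_paths, (str, Path)):
        hmm_paths = [hmm_paths]
    target = target_protein.upper().rstrip("*")
    aligner = _consensus_aligner()
    ins_prob: dict[int, float] = {}
    del_prob: dict[int, float] = {}
    sources: list[str] = []
    for path in hmm_paths:
        with pyhmmer.plan7.HMMFile(str(path)) as fh:
            hmms = list(fh)
        precise = _text_transitions(path)
        for idx, hmm in enumerate(hmms):
            if hmm.consensus is None:
                raise ValueError(f"{path}: profile has no consensus line")
            sources.append(hmm.name.decode() if isinstance(hmm.name, bytes) else str(hmm.name))
            consensus = hmm.consensus.upper()
            trans = np.asarray(hmm.transition_probabilities)
            # rows 0..M; columns: m->m, m->i, m->d, i->m, i->i, d->m, d->d
            mi = trans[1:, 1]
            md = trans[1:, 2]
            if idx < len(precise) and precise[idx][0].size == mi.size:
                mi, md = precise[idx]
            alns = aligner.align(target, consensus)
            aln = alns[0]
            mapped = 0
            t_blocks, q_blocks = aln.aligned
            for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
                for offset in range(t1 - t0):
                    state = int(q0 + offset)  # 0-based match state index
                    pos = int(t0 + offset + 1)  # 1-based target position
                    if pos in ins_prob:
                        continue
                    ins_prob[pos] = float(mi[state])
                    del_prob[pos] = float(md[state])
                    mapped += 1
            if mapped < 0.5 * len(consensus):
                warnings.warn(
                    f"{sources[-1]}: only {mapped}/{len(consensus)} match states "
                    "aligned to the target"
                )
    return HMMIndelProfile(ins_prob=ins_prob, del_prob=del_prob, sources=sources)


def indel_conservation_test(
    st: ScoreTable,
    prof: HMMIndelProfile,
    threshold: float = 0.1,
) -> dict[str, dict]:
    """Fisher's exact association of tolerated vs evolutionarily observed indels.

    Profile probabilities are pseudo-binary, so they are binarized at
    ``threshold`` into observed / not observed; positions are
    cross-tabulated against the sign of their mean experimental indel
    score (non-negative = tolerated). One 2x2 table and two-sided Fisher
    exact p per indel type. A degenerate table (empty row or column)
    yields p = 1 with a warning.
    """
    df = st.df[np.isfinite(st.df["score"])]
    out: dict[str, dict] = {}
    for kind, probs in (("insertion", prof.ins_prob), ("deletion", prof.del_prob)):
        means = df[df["kind"] == kind].groupby("position")["score"].mean()
        positions = [p for p in means.index if p in probs]
        table = np.zeros((2, 2), dtype=int)
        for p in positions:
            observed = probs[p] >= threshold
            positive = means.loc[p] >= 0
            table[0 if observed else 1, 0 if positive else 1] += 1
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            warnings.warn(f"{kind}: degenerate contingency table; p set to 1")
            pval = 1.0
        else:
            pval = fisher_exact_two_sided(table)
        out[kind] = {"table": table, "p": float(pval), "n": int(table.sum())}
    return out
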