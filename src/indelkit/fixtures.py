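"""Deterministic synthetic data: genes, count tables, score tables, profiles.

Everything downstream of the designer is testable without any external
download: :func:`random_gene` builds GC-controlled random ORFs,
:func:`simulate_counts` emulates a variant-calling count table with a
configurable off-target read fraction and error-class mix (real oligo
pools carry synthesis errors — mostly deletions — so that only ~80% of
reads are designed variants), and :func:`simulate_scores` draws per-variant
fitness scores with a configurable per-kind effect hierarchy (deletions
most disruptive, then insertions, missense, synonymous) plus a shared
per-position effect and noise. :func:`write_hmm_profile` emits a small
synthetic HMMER3 profile with chosen match->insert / match->delete
transition probabilities.

All generators are seeded and fully reproducible: identical configuration
and seed give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design_core import Design
from .sequence_model import AA_TO_CODONS, CODON_TO_AA, TargetGene, make_target_gene

__all__ = [
    "SimConfig",
    "random_gene",
    "simulate_counts",
    "simulate_scores",
    "write_hmm_profile",
    "DEFAULT_OFFTARGET_MIX",
]

#: off-target error-class mix: synthesis errors are dominated by deletions,
#: followed by mismatches and multi-error reads
DEFAULT_OFFTARGET_MIX: dict[str, float] = {
    "del_1": 0.20,
    "del_2_3": 0.12,
    "del_4_30": 0.18,
    "del_gt30": 0.10,
    "ins_1": 0.06,
    "ins_2_3": 0.04,
    "ins_4_30": 0.03,
    "ins_gt30": 0.02,
    "synonymous_point": 0.05,
    "missense_point": 0.10,
    "multiple": 0.10,
}

#: per-kind fitness means: deletions < insertions < missense < synonymous
DEFAULT_KIND_MEANS: dict[str, float] = {
    "deletion": -2.0,
    "insertion": -1.0,
    "missense": -0.5,
    "synonymous": 0.0,
    "stop": -2.5,
}


@dataclass
class SimConfig:
    """Shared knobs for the synthetic generators.

    ``mixing_sigma`` is the standard deviation of the log-normal
    per-sublibrary mixing factor (manual sub-pool mixing is the dominant
    source of positional bias in real libraries). ``offtarget_fraction``
    is the expected share of reads that are not designed variants.
    ``position_sigma`` scales a per-position effect shared by all variant
    kinds at that position; together with ``score_noise_sigma`` it sets
    the correlation between same-position variant scores.
    """

    seed: int = 0
    n_codons: int = 100
    gc: float = 0.50
    depth: int = 1_000_000
    offtarget_fraction: float = 0.20
    offtarget_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OFFTARGET_MIX))
    n_offtarget_genotypes: int = 150
    mixing_sigma: float = 0.30
    kind_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_KIND_MEANS))
    position_sigma: float = 0.5
    score_noise_sigma: float = 0.2
    replicates: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.offtarget_fraction <= 1:
            raise ValueError("offtarget_fraction must be in [0, 1]")
        if self.mixing_sigma < 0 or self.score_noise_sigma < 0 or self.position_sigma < 0:
            raise ValueError("sigmas must be non-negative")


_GC_COUNT = {c: (c.count("G") + c.count("C")) for aa in AA_TO_CODONS for c in AA_TO_CODONS[aa]}


def random_gene(
    n_codons: int = 100,
    gc: float = 0.50,
    seed: int = 0,
    name: str | None = None,
    terminal_stop: bool = True,
) -> TargetGene:
    """A random valid ORF with GC content within 3% of the target.

    ``n_codons`` counts coding residues (ATG start included; a terminal
    stop codon is appended by default and excluded from the mutagenesis
    window). Codons are chosen per residue to steer the running GC count
    toward the target. Reproducible: same arguments, same sequence.
    """
    if n_codons < 10:
        raise ValueError("need at least 10 codons")
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    protein = "M" + "".join(rng.choice(list(aas), size=n_codons - 1))
    codons: list[str] = []
    gc_count = 0
    total = 0
    for i, aa in enumerate(protein):
        options = AA_TO_CODONS[aa]
        deficit = gc * (total + 3) - gc_count
        scores = np.array([abs(_GC_COUNT[c] - deficit) for c in options])
        best = np.flatnonzero(scores == scores.min())
        codon = options[int(rng.choice(best))]
        codons.append(codon)
        gc_count += _GC_COUNT[codon]
        total += 3
    if terminal_stop:
        deficit = gc * (total + 3) - gc_count
        stop = min(("TAA", "TAG", "TGA"), key=lambda c: abs(_GC_COUNT[c] - deficit))
        codons.append(stop)

    # extreme targets can be out of reach for an unlucky amino acid draw;
    # swap random internal residues toward GC-compatible amino acids
    gc_rich = [aa for aa in aas if max(_GC_COUNT[c] for c in AA_TO_CODONS[aa]) == 3]
    gc_poor = [aa for aa in aas if min(_GC_COUNT[c] for c in AA_TO_CODONS[aa]) == 0]
    total_nt = 3 * len(codons)
    for _ in range(4 * n_codons):
        realized = sum(_GC_COUNT[c] for c in codons) / total_nt
        if abs(realized - gc) <= 0.02:
            break
        i = int(rng.integers(1, n_codons))  # never the start codon or stop
        pool = gc_rich if realized < gc else gc_poor
        aa = pool[int(rng.integers(0, len(pool)))]
        key = (lambda c: -_GC_COUNT[c]) if realized < gc else (lambda c: _GC_COUNT[c])
        codons[i] = sorted(AA_TO_CODONS[aa], key=key)[0]

    cds = "".join(codons)
    realized = (cds.count("G") + cds.count("C")) / len(cds)
    if abs(realized - gc) > 0.03:
        raise ValueError(
            f"GC target {gc:.2f} infeasible for {n_codons} codons (realized {realized:.3f})"
        )
    return make_target_gene(name or f"rand{seed}_{n_codons}", cds)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------


def _random_offtarget_signature(
    cls: str, cds: str, rng: np.random.Generator, forbidden: set[str]
) -> str:
    """One off-target genotype string of the given error class."""
    bases = "ACGT"
    n = len(cds)
    for _ in range(200):
        if cls.startswith("del_"):
            lo, hi = {"del_1": (1, 1), "del_2_3": (2, 3), "del_4_30": (4, 30), "del_gt30": (31, 60)}[cls]
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(1, n - length))
            sig = f"{start}_{start + length - 1}del"
        elif cls.startswith("ins_"):
            lo, hi = {"ins_1": (1, 1), "ins_2_3": (2, 3), "ins_4_30": (4, 30), "ins_gt30": (31, 60)}[cls]
            length = int(rng.integers(lo, hi + 1))
            pos = int(rng.integers(1, n))
            payload = "".join(bases[i] for i in rng.integers(0, 4, size=length))
            sig = f"{pos}_{pos + 1}ins{payload}"
        elif cls == "synonymous_point":
            ci = int(rng.integers(0, n // 3))
            old_codon = cds[3 * ci : 3 * ci + 3]
            syns = [c for c in AA_TO_CODONS[CODON_TO_AA[old_codon]]
                    if c != old_codon and sum(a != b for a, b in zip(c, old_codon)) == 1]
            if not syns:
                continue
            new_codon = syns[int(rng.integers(0, len(syns)))]
            j = next(k for k in range(3) if old_codon[k] != new_codon[k])
            sig = f"{3 * ci + j + 1}{old_codon[j]}>{new_codon[j]}"
        elif cls == "missense_point":
            pos = int(rng.integers(1, n + 1))
            old = cds[pos - 1]
            new = bases[int(rng.integers(0, 4))]
            if new == old:
                continue
            codon_i = (pos - 1) // 3
            codon = cds[3 * codon_i : 3 * codon_i + 3]
            mutated = codon[: (pos - 1) % 3] + new + codon[(pos - 1) % 3 + 1 :]
            if CODON_TO_AA[mutated] == CODON_TO_AA[codon]:
                continue
            sig = f"{pos}{old}>{new}"
        elif cls == "multiple":
            ops = []
            for _k in range(2):
                pos = int(rng.integers(1, n + 1))
                old = cds[pos - 1]
                new = bases[int(rng.integers(0, 4))]
                if new == old:
                    new = bases[(bases.index(old) + 1) % 4]
                ops.append((pos, f"{pos}{old}>{new}"))
            ops.sort()
            if ops[0][0] == ops[1][0]:
                continue
            sig = ";".join(op for _p, op in ops)
        else:
            raise ValueError(f"unknown off-target class {cls!r}")
        if sig not in forbidden:
            return sig
    raise RuntimeError(f"could not draw an off-target signature for class {cls}")


def simulate_counts(design: Design, cfg: SimConfig) -> pd.DataFrame:
    """Simulated variant-caller output: columns ``genotype``, ``count``.

    Designed variants receive multinomial reads with per-sublibrary
    log-normal mixing factors ``exp(sigma * z_s)`` (``z`` drawn once per
    sublibrary, so the factor is monotone in sigma under a fixed seed);
    off-target genotypes are injected at the configured read fraction and
    class mix.
    """
    rng = np.random.default_rng(cfg.seed)
    names = [v.name for v in design.variants if v.name in design.oligos]
    subs = np.array([design.oligos[n].sublibrary for n in names])
    z = rng.standard_normal(len(design.sublibraries))
    factors = np.exp(cfg.mixing_sigma * z)
    weights = factors[subs - 1]
    probs = weights / weights.sum()

    n_off = rng.binomial(cfg.depth, cfg.offtarget_fraction)
    designed_counts = rng.multinomial(cfg.depth - n_off, probs)

    designed_sigs = {design.oligos[n].signature for n in names}
    mix = cfg.offtarget_mix
    mix_total = sum(mix.values())
    classes = list(mix)
    class_p = np.array([mix[c] / mix_total for c in classes])
    per_class = np.maximum(
        np.round(class_p * cfg.n_offtarget_genotypes).astype(int), 1
    )
    off_sigs: list[str] = []
    off_class_p: list[float] = []
    seen: set[str] = set(designed_sigs)
    for cls, m, p in zip(classes, per_class, class_p):
        for _ in range(m):
            sig = _random_offtarget_signature(cls, design.gene.cds, rng, seen)
            seen.add(sig)
            off_sigs.append(sig)
            off_class_p.append(p / m)
    off_p = np.array(off_class_p)
    off_counts = rng.multinomial(n_off, off_p / off_p.sum()) if n_off else np.zeros(len(off_sigs), int)

    rows = [
        {"genotype": design.oligos[n].signature, "count": int(c)}
        for n, c in zip(names, designed_counts)
    ]
    rows += [
        {"genotype": s, "count": int(c)} for s, c in zip(off_sigs, off_counts) if c > 0
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Score simulation
# ---------------------------------------------------------------------------


def simulate_scores(design: Design, cfg: SimConfig) -> pd.DataFrame:
    """Simulated per-variant fitness scores in the Enrich2 output layout.

    ``score = kind_mean + position_effect + noise``; the position effect is
    shared by every variant at a position, so same-position scores of two
    kinds correlate with ``rho = position_sigma^2 / (position_sigma^2 +
    noise_sigma^2)``. With ``replicates > 0`` the table gains
    ``score_rep{i}`` columns and ``score`` is their mean.
    """
    rng = np.random.default_rng(cfg.seed)
    n_pos = design.gene.n_residues
    pos_eff = rng.normal(0.0, cfg.position_sigma, size=n_pos + 1)
    rows = []
    for v in design.variants:
        base = cfg.kind_means.get(v.kind, 0.0) + pos_eff[v.codon_pos]
        if cfg.replicates > 0:
            reps = base + rng.normal(0.0, cfg.score_noise_sigma, size=cfg.replicates)
            score = float(np.mean(reps))
            se = float(np.std(reps, ddof=1) / np.sqrt(cfg.replicates)) if cfg.replicates > 1 else 0.0
            row = {"hgvs": v.name, "score": score, "SE": se}
            row.update({f"score_rep{i + 1}": float(r) for i, r in enumerate(reps)})
        else:
            score = base + float(rng.normal(0.0, cfg.score_noise_sigma))
            row = {"hgvs": v.name, "score": score, "SE": cfg.score_noise_sigma}
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic HMMER3 profiles
# ---------------------------------------------------------------------------

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def _enc(p: float) -> str:
    return "*" if p <= 0 else f"{-np.log(p):.9f}"


def write_hmm_profile(
    path: str | Path,
    consensus: str,
    m2i: list[float] | np.ndarray,
    m2d: list[float] | np.ndarray,
    name: str = "synthetic",
) -> Path:
    """Write a small synthetic HMMER3 ASCII profile.

    Match-state emissions put 90% of the probability on the consensus
    residue; ``m2i[k]`` / ``m2d[k]`` are the match->insert and
    match->delete transition probabilities of match state ``k+1`` (encoded
    in the file as negative natural logs, HMMER's convention). Intended
    for tests and demonstrations, not as a real family model.
    """
    consensus = consensus.upper()
    m = len(consensus)
    if len(m2i) != m or len(m2d) != m:
        raise ValueError("m2i/m2d must match consensus length")
    lines = [
        "HMMER3/f [3.4 | Aug 2023]",
        f"NAME  {name}",
        f"LENG  {m}",
        "ALPH  amino",
        "RF    no",
        "MM    no",
        "CONS  yes",
        "CS    no",
        "MAP   yes",
        "HMM          "
        + "        ".join(_AA_ORDER)
        + "",
        "            m->m     m->i     m->d     i->m     i->i     d->m     d->d",
    ]
    bg = [_enc(1 / 20.0)] * 20
    lines.append("  COMPO   " + "  ".join(bg))
    lines.append("          " + "  ".join(bg))
    # node 0 (begin) transitions: B->M1, B->I0, B->D1
    lines.append(
        "          "
        + "  ".join([_enc(0.96), _enc(0.02), _enc(0.02), _enc(0.5), _enc(0.5), _enc(1.0), "*"])
    )
    for k in range(1, m + 1):
        aa = consensus[k - 1]
        ems = []
        for a in _AA_ORDER:
            p = 0.9 if a == aa else 0.1 / 19.0
            ems.append(_enc(p))
        lines.append(f"{k:7d}   " + "  ".join(ems) + f"{k:7d} {aa.lower()} - - -")
        lines.append("          " + "  ".join(bg))
        mi = float(m2i[k - 1])
        md = float(m2d[k - 1]) if k < m else 0.0
        mm = 1.0 - mi - md
        if mm <= 0:
            raise ValueError("m->i + m->d must be < 1")
        if k < m:
            trans = [_enc(mm), _enc(mi), _enc(md), _enc(0.5), _enc(0.5), _enc(0.5), _enc(0.5)]
        else:
            trans = [_enc(mm), _enc(mi), "*", _enc(0.5), _enc(0.5), _enc(1.0), "*"]
        lines.append("          " + "  ".join(trans))
    lines.append("//")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
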