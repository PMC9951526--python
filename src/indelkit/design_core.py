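"""Library design: partitioning, variant enumeration, oligos, and primers.

The designer turns a domesticated :class:`~indelkit.sequence_model.TargetGene`
into a synthesis-ready oligo pool:

1. :func:`partition_gene` tiles the mutagenesis window into sublibrary
   fragments sized to the synthesis platform (230-nt oligos by default).
2. :func:`select_overhangs` assigns each fragment junction a wild-type
   4-nt Golden Gate overhang, sliding cut sites by a few nucleotides where
   needed so that all overhangs in the design are pairwise distinct,
   non-palindromic, and not reverse complements of one another.
3. :func:`enumerate_variants` lists every programmed variant: 19 missense
   per residue, one synonymous codon swap where the amino acid allows it,
   an optional stop, multi-codon insertions (Gly / Gly-Ser / Gly-Ser-Gly
   by default) after every residue, and 1-3 codon deletions at every
   eligible start position (never the start codon, stopping short of the
   C terminus by the maximum deletion length).
4. :func:`design_primers` picks orthogonal subpool barcode primer pairs and
   inverse-PCR backbone pairs whose tails install complementary cut sites.
5. :func:`build_oligo` lays each variant out as
   ``primer | buffer | cassette | fragment(flank+payload+flank) | cassette |
   buffer | primer``, buffering every oligo of a sublibrary to one common
   synthesis length so amplification does not favour shorter species.

:func:`design_library` runs the whole pipeline and returns a
:class:`Design` that the assembly simulator can audit end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from .sequence_model import (
    AA_TO_CODONS,
    BSAI,
    BSMBI,
    CODON_TO_AA,
    DEFAULT_ENZYMES,
    STANDARD_AAS,
    CodonUsageTable,
    EnzymeProfile,
    TargetGene,
    UndomesticatableSite,
    domesticate,
    reverse_complement,
    scan_sites,
    translate,
)

__all__ = [
    "GeometryConfig",
    "VariantConfig",
    "Sublibrary",
    "VariantSpec",
    "Oligo",
    "PrimerPair",
    "Design",
    "DesignError",
    "NoValidOverhangs",
    "NoSafeCodon",
    "OligoTooLong",
    "OligoBuildError",
    "PrimerDesignFailure",
    "platform_limits",
    "max_mutable_codons",
    "partition_gene",
    "select_overhangs",
    "enumerate_variants",
    "choose_codon",
    "design_primers",
    "build_oligo",
    "design_library",
]


class DesignError(RuntimeError):
    """Base class for library-design failures."""


class NoValidOverhangs(DesignError):
    """No junction slide assignment satisfies the overhang constraints."""


class NoSafeCodon(DesignError):
    """Every codon for the requested amino acid creates an enzyme site."""


class OligoTooLong(DesignError):
    """A zero-buffer oligo already exceeds the synthesis length limit."""


class OligoBuildError(DesignError):
    """A variant's oligo could not be built (e.g. unresolvable new site)."""


class PrimerDesignFailure(DesignError):
    """No annealing region within the length cap reaches the Tm threshold."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometryConfig:
    """Synthesis-platform geometry.

    Defaults describe a 230-nt microarray oligo platform: 18-nt subpool
    primer binding sites, an 11-nt Type IIS cassette footprint per side
    (6-nt recognition + 1-nt spacer + 4-nt overhang), four non-mutated
    wild-type codons flanking each cut site, and enforced payload limits
    of 120 nt for insertions and 27 nt for deletions.
    """

    max_oligo_len: int = 230
    primer_len: int = 18
    cassette_len: int = 11
    flank_codons: int = 4
    max_ins_payload: int = 120
    max_del_span: int = 27

    def __post_init__(self) -> None:
        if self.max_oligo_len < 2 * (self.primer_len + self.cassette_len) + 6 * self.flank_codons + 3:
            raise ValueError("geometry infeasible: oligo cannot hold primers, cassettes, flanks and one codon")
        if self.payload_budget <= 0:
            raise ValueError("geometry infeasible: non-positive payload budget")

    @property
    def payload_budget(self) -> int:
        """Nucleotides available between the two primer+cassette blocks."""
        return self.max_oligo_len - 2 * (self.primer_len + self.cassette_len)


@dataclass(frozen=True)
class VariantConfig:
    """Which variant classes to program.

    ``insertion_payloads`` are nucleotide strings (in-frame); the defaults
    encode G, GS, and GSG with top-ranked human codons. ``deletion_lengths``
    are codon counts. Stop codons are off by default.
    """

    include_missense: bool = True
    include_synonymous: bool = True
    include_stop: bool = False
    deletion_lengths: tuple[int, ...] = (1, 2, 3)
    insertion_payloads: tuple[str, ...] = ("GGC", "GGCAGC", "GGCAGCGGC")

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.deletion_lengths):
            raise ValueError("deletion lengths must be positive codon counts")
        for p in self.insertion_payloads:
            if len(p) % 3:
                raise ValueError(f"insertion payload {p!r} is not a whole number of codons")
            if set(p) - set("ACGT"):
                raise ValueError(f"insertion payload {p!r} contains non-ACGT characters")

    @property
    def max_deletion_codons(self) -> int:
        return max(self.deletion_lengths, default=0)

    @property
    def max_insertion_nt(self) -> int:
        return max((len(p) for p in self.insertion_payloads), default=0)

    def validate_against(self, geom: GeometryConfig) -> None:
        """Enforce the synthesis platform's indel payload limits."""
        max_ins, max_del = platform_limits(geom)
        if self.max_insertion_nt > max_ins:
            raise ValueError(
                f"insertion payload of {self.max_insertion_nt} nt exceeds the "
                f"platform limit of {max_ins} nt"
            )
        if 3 * self.max_deletion_codons > max_del:
            raise ValueError(
                f"deletion span of {3 * self.max_deletion_codons} nt exceeds the "
                f"platform limit of {max_del} nt"
            )


def platform_limits(geom: GeometryConfig) -> tuple[int, int]:
    """(max insertion nt, max deletion nt) enforced by the synthesis profile."""
    return geom.max_ins_payload, geom.max_del_span


def max_mutable_codons(
    geom: GeometryConfig, enzyme: EnzymeProfile, vcfg: VariantConfig
) -> int:
    """Largest mutable window (codons) that fits one oligo.

    The oligo must hold, per side, the primer plus recognition+spacer (the
    4-nt overhang is wild-type gene sequence and already counted inside the
    fragment), both 4-codon flanks, the window itself, and the longest
    configured insertion payload. At the defaults this is
    ``floor((230 - 2*25 - 24 - 9) / 3) = 49`` codons.
    """
    per_side = geom.primer_len + (geom.cassette_len - enzyme.overhang_len)
    budget = geom.max_oligo_len - 2 * per_side - 6 * geom.flank_codons - vcfg.max_insertion_nt
    return budget // 3


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass
class Sublibrary:
    """One mutagenic fragment window and its junction bookkeeping.

    ``up_slide`` shifts the 5' cut site right (+, inward) or left (-,
    outward) of its default position 4 codons upstream of the window;
    ``down_slide`` shifts the 3' cut site right (+, outward) / left (-,
    inward) of its default 4 codons downstream.
    """

    index: int
    codon_start: int
    codon_end: int
    up_slide: int = 0
    down_slide: int = 0
    up_overhang: str = ""
    down_overhang: str = ""
    barcode_fwd: str = ""
    barcode_rev: str = ""

    @property
    def n_codons(self) -> int:
        return self.codon_end - self.codon_start + 1


@dataclass(frozen=True)
class VariantSpec:
    """One programmed edit.

    ``payload`` is an amino acid for missense/stop, the replacement codon
    for synonymous, and the inserted nucleotide string for insertions.
    ``span`` is the deleted codon count for deletions (0 otherwise).
    ``codon_pos`` is the 1-based residue the edit applies to (insertions go
    immediately 3' of it; deletions start at it).
    """

    kind: str  # missense | synonymous | stop | insertion | deletion
    codon_pos: int
    payload: str = ""
    span: int = 0
    name: str = ""


@dataclass(frozen=True)
class Oligo:
    """One synthesized sequence with its layout breakdown.

    ``layout`` is an ordered tuple of ``(segment_label, length)`` covering
    the whole sequence. ``signature`` is the variant's nucleotide-level
    genotype relative to the wild-type CDS (semicolon-joined operations,
    e.g. ``"84_85insGGC"`` or ``"82G>C;84T>G"``), including any synonymous
    rescue edits needed to keep the fragment free of internal enzyme sites.
    """

    variant_name: str
    sublibrary: int
    sequence: str
    layout: tuple[tuple[str, int], ...]
    signature: str


@dataclass(frozen=True)
class PrimerPair:
    kind: str  # subpool | backbone
    sublibrary: int
    fwd: str
    rev: str
    fwd_anneal: str
    rev_anneal: str
    fwd_tm: float
    rev_tm: float


@dataclass
class Design:
    """A complete library design against one target construct."""

    gene: TargetGene
    geom: GeometryConfig
    vcfg: VariantConfig
    usage: CodonUsageTable
    enzyme: EnzymeProfile
    up_ctx: str
    down_ctx: str
    sublibraries: list[Sublibrary] = field(default_factory=list)
    variants: list[VariantSpec] = field(default_factory=list)
    oligos: dict[str, Oligo] = field(default_factory=dict)
    primers: list[PrimerPair] = field(default_factory=list)
    domestication_edits: list[tuple[int, str, str]] = field(default_factory=list)
    build_failures: dict[str, str] = field(default_factory=dict)

    @property
    def construct(self) -> str:
        return self.up_ctx + self.gene.cds + self.down_ctx

    @property
    def cds_offset(self) -> int:
        """0-based offset of the CDS within the construct."""
        return len(self.up_ctx)

    def fragment_span(self, sub: Sublibrary) -> tuple[int, int]:
        """0-based half-open [start, end) of the wild-type fragment."""
        u = self.cds_offset
        f = 3 * self.geom.flank_codons
        start = u + 3 * (sub.codon_start - 1) - f + sub.up_slide
        end = u + 3 * sub.codon_end + f + sub.down_slide
        return start, end

    def sublibrary_for(self, codon_pos: int) -> Sublibrary:
        for sub in self.sublibraries:
            if sub.codon_start <= codon_pos <= sub.codon_end:
                return sub
        raise KeyError(f"codon {codon_pos} is outside every sublibrary window")

    def common_oligo_len(self, sub: Sublibrary) -> int:
        """The shared synthesis length of every oligo in ``sub``."""
        start, end = self.fragment_span(sub)
        per_side = self.geom.primer_len + len(self.enzyme.recognition) + self.enzyme.spacer_len
        return 2 * per_side + (end - start) + self.vcfg.max_insertion_nt


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------


def partition_gene(
    gene: TargetGene,
    geom: GeometryConfig | None = None,
    vcfg: VariantConfig | None = None,
    enzyme: EnzymeProfile = BSAI,
) -> list[Sublibrary]:
    """Tile the mutagenesis window into near-equal sublibrary windows.

    The number of sublibraries is ``ceil(window / max_mutable_codons)`` and
    window sizes differ by at most one codon.
    """
    geom = geom or GeometryConfig()
    vcfg = vcfg or VariantConfig()
    vcfg.validate_against(geom)
    w = gene.window_codons
    if w < 1:
        raise DesignError("mutagenesis window smaller than one codon")
    maxw = max_mutable_codons(geom, enzyme, vcfg)
    if maxw < 1:
        raise DesignError("geometry infeasible: no room for a mutable codon")
    n = math.ceil(w / maxw)
    base, extra = divmod(w, n)
    if vcfg.deletion_lengths and n > 1 and base < vcfg.max_deletion_codons + 1:
        raise DesignError("sublibrary windows smaller than the maximum deletion span")
    subs: list[Sublibrary] = []
    start = gene.mut_start
    for i in range(n):
        size = base + (1 if i < extra else 0)
        subs.append(Sublibrary(index=i + 1, codon_start=start, codon_end=start + size - 1))
        start += size
    return subs


# ---------------------------------------------------------------------------
# Overhang selection
# ---------------------------------------------------------------------------


def _overhang_ok(cand: str, used: set[str]) -> bool:
    rc = reverse_complement(cand)
    return cand != rc and cand not in used and rc not in used


def _junction_candidates(
    design: Design, sub: Sublibrary, side: str
) -> list[int]:
    """Ordered candidate slides for one junction, smallest |shift| first.

    Inward slides keep the overhang inside the non-mutated flank; on the 3'
    side of internal junctions they are additionally capped so that a
    deletion starting at the last window codon can never reach the
    overhang. Outward slides lengthen the fragment and are only offered
    while the sublibrary retains synthesis-length slack.
    """
    geom, vcfg = design.geom, design.vcfg
    flank_nt = 3 * geom.flank_codons
    oh = design.enzyme.overhang_len
    intrusion = 3 * max(vcfg.max_deletion_codons - 1, 0)
    inward_max = flank_nt - oh
    last = design.sublibraries[-1].index if design.sublibraries else sub.index
    if side == "down" and vcfg.deletion_lengths and sub.index != last:
        inward_max = max(flank_nt - oh - intrusion, 0)
    slack = geom.max_oligo_len - design.common_oligo_len(sub)
    outward_max = min(flank_nt, max(slack, 0))

    out: list[int] = [0]
    for s in range(1, max(inward_max, outward_max) + 1):
        if s <= inward_max:
            out.append(s if side == "up" else -s)  # inward
        if s <= outward_max:
            out.append(-s if side == "up" else s)  # outward
    return out


def select_overhangs(design: Design) -> None:
    """Assign junction overhangs to every sublibrary, in place.

    A depth-first search over per-junction slide candidates finds an
    assignment in which every overhang 4-mer across the design is unique,
    non-palindromic, and no two are reverse complements.
    """
    construct = design.construct
    oh = design.enzyme.overhang_len
    junctions: list[tuple[Sublibrary, str]] = []
    for sub in design.sublibraries:
        junctions.append((sub, "up"))
        junctions.append((sub, "down"))

    def fourmer(sub: Sublibrary, side: str, slide: int) -> str:
        saved = (sub.up_slide, sub.down_slide)
        if side == "up":
            sub.up_slide = slide
        else:
            sub.down_slide = slide
        start, end = design.fragment_span(sub)
        sub.up_slide, sub.down_slide = saved
        return construct[start : start + oh] if side == "up" else construct[end - oh : end]

    budget = [200_000]  # node budget guards against pathological inputs

    def solve(i: int, used: set[str]) -> bool:
        if i == len(junctions):
            return True
        sub, side = junctions[i]
        for slide in _junction_candidates(design, sub, side):
            budget[0] -= 1
            if budget[0] < 0:
                return False
            cand = fourmer(sub, side, slide)
            if not _overhang_ok(cand, used):
                continue
            if side == "up":
                sub.up_slide, sub.up_overhang = slide, cand
            else:
                sub.down_slide, sub.down_overhang = slide, cand
            used.add(cand)
            used.add(reverse_complement(cand))
            if solve(i + 1, used):
                return True
            used.discard(cand)
            used.discard(reverse_complement(cand))
            if side == "up":
                sub.up_slide, sub.up_overhang = 0, ""
            else:
                sub.down_slide, sub.down_overhang = 0, ""
        return False

    if not solve(0, set()):
        raise NoValidOverhangs(
            f"{design.gene.name}: no slide assignment yields a mutually "
            "compatible overhang set"
        )


# ---------------------------------------------------------------------------
# Variant enumeration
# ---------------------------------------------------------------------------


def _insertion_name(wt_aa: str, pos: int, payload_nt: str) -> str:
    return f"p.{wt_aa}{pos}_ins{translate(payload_nt)}"


def _deletion_name(protein: str, pos: int, span: int) -> str:
    if span == 1:
        return f"p.{protein[pos - 1]}{pos}del"
    return f"p.{protein[pos - 1]}{pos}_{protein[pos + span - 2]}{pos + span - 1}del"


def enumerate_variants(
    gene: TargetGene,
    vcfg: VariantConfig | None = None,
    usage: CodonUsageTable | None = None,
    geom: GeometryConfig | None = None,
) -> list[VariantSpec]:
    """List every programmed variant for the gene's mutagenesis window.

    Per residue: 19 missense substitutions; one synonymous swap when the
    wild-type amino acid has at least two codons; an optional stop; one
    insertion per configured payload (placed 3' of the residue); and one
    deletion per configured length starting at the residue, provided the
    start is not codon 1 and the start does not exceed ``L - max(deletion
    lengths)`` (L = residue count), so deletions stop short of the C
    terminus.
    """
    vcfg = vcfg or VariantConfig()
    usage = usage or CodonUsageTable.default()
    if geom is not None:
        vcfg.validate_against(geom)
    prot = gene.protein
    n_res = gene.n_residues
    max_del = vcfg.max_deletion_codons
    del_last_start = n_res - max_del
    out: list[VariantSpec] = []
    for p in range(gene.mut_start, gene.mut_end + 1):
        wt = prot[p - 1]
        if wt == "*":
            continue
        if vcfg.include_missense:
            for aa in STANDARD_AAS:
                if aa != wt:
                    out.append(VariantSpec("missense", p, aa, 0, f"p.{wt}{p}{aa}"))
        if vcfg.include_synonymous and len(AA_TO_CODONS[wt]) >= 2:
            alt = usage.synonyms(gene.codon(p))[0]
            out.append(VariantSpec("synonymous", p, alt, 0, f"p.{wt}{p}="))
        if vcfg.include_stop:
            out.append(VariantSpec("stop", p, "*", 0, f"p.{wt}{p}*"))
        for payload in vcfg.insertion_payloads:
            out.append(VariantSpec("insertion", p, payload, 0, _insertion_name(wt, p, payload)))
        if 2 <= p <= del_last_start:
            for k in vcfg.deletion_lengths:
                out.append(VariantSpec("deletion", p, "", k, _deletion_name(prot, p, k)))
    names = [v.name for v in out]
    if len(set(names)) != len(names):
        raise DesignError("duplicate variant names in enumeration")
    return out


# ---------------------------------------------------------------------------
# Codon choice
# ---------------------------------------------------------------------------


def choose_codon(
    aa: str,
    usage: CodonUsageTable,
    context5: str,
    context3: str,
    enzymes: Sequence[EnzymeProfile] = DEFAULT_ENZYMES,
    exclude: Iterable[str] = (),
) -> str:
    """Highest-usage codon for ``aa`` that creates no enzyme site in context.

    Only sites overlapping the candidate codon are considered (the flanking
    context is taken as given). Deterministic; raises :class:`NoSafeCodon`
    when every codon would complete a recognition site.
    """
    reach = max(len(e.recognition) for e in enzymes) - 1
    left = context5[-reach:] if reach else ""
    right = context3[:reach] if reach else ""
    excluded = set(exclude)
    for codon, _freq in usage.codons_for(aa):
        if codon in excluded:
            continue
        window = left + codon + right
        span = (len(left) + 1, len(left) + 3)  # 1-based codon span in window
        safe = True
        for enz, _strand, off in scan_sites(window, enzymes) if window else []:
            site = (off, off + len(enz.recognition) - 1)
            if site[0] <= span[1] and site[1] >= span[0]:
                safe = False
                break
        if safe:
            return codon
    raise NoSafeCodon(f"no codon for {aa} avoids enzyme sites in this context")


def _choose_codon_or_least_bad(
    aa: str,
    usage: CodonUsageTable,
    context5: str,
    context3: str,
    enzymes: Sequence[EnzymeProfile] = DEFAULT_ENZYMES,
    exclude: Iterable[str] = (),
) -> str:
    """:func:`choose_codon`, falling back to the fewest-site codon.

    When every codon completes a recognition site, the site has to be
    removed afterwards by recoding a neighboring codon (site rescue), so
    the codon creating the fewest sites is still usable.
    """
    try:
        return choose_codon(aa, usage, context5, context3, enzymes, exclude)
    except NoSafeCodon:
        reach = max(len(e.recognition) for e in enzymes) - 1
        left, right = context5[-reach:], context3[:reach]
        excluded = set(exclude)
        best, best_n = None, None
        for codon, _freq in usage.codons_for(aa):
            if codon in excluded:
                continue
            n = len(scan_sites(left + codon + right, enzymes))
            if best_n is None or n < best_n:
                best, best_n = codon, n
        if best is None:
            raise
        return best


# ---------------------------------------------------------------------------
# Oligo construction
# ---------------------------------------------------------------------------

_FILLER_POOL_LEN = 6000


def _make_filler_pool(enzymes: Sequence[EnzymeProfile]) -> str:
    """Deterministic pseudorandom filler, 40-60% GC, free of enzyme sites."""
    rng = np.random.default_rng(1121)
    bases = "ACGT"
    chunks: list[str] = []
    total = 0
    while total < _FILLER_POOL_LEN:
        idx = rng.integers(0, 4, size=200)
        chunk = "".join(bases[i] for i in idx)
        gc = (chunk.count("G") + chunk.count("C")) / len(chunk)
        if not 0.40 <= gc <= 0.60:
            continue
        cand = ("".join(chunks)) + chunk
        if scan_sites(cand, enzymes):
            continue
        chunks.append(chunk)
        total += len(chunk)
    return "".join(chunks)


_FILLER_CACHE: dict[tuple[str, ...], str] = {}


def _filler_pool(enzymes: Sequence[EnzymeProfile]) -> str:
    key = tuple(sorted(e.recognition for e in enzymes))
    if key not in _FILLER_CACHE:
        _FILLER_CACHE[key] = _make_filler_pool(enzymes)
    return _FILLER_CACHE[key]


def _primer_kmers(design: Design, k: int = 12) -> set[str]:
    kmers: set[str] = set()
    for pp in design.primers:
        for seq in (pp.fwd, pp.rev):
            for s in (seq, reverse_complement(seq)):
                kmers.update(s[i : i + k] for i in range(len(s) - k + 1))
    return kmers


def _apply_edit(
    design: Design, variant: VariantSpec
) -> tuple[str, int, list[tuple[int, str, str]], str]:
    """Apply the programmed edit to the CDS.

    Returns ``(edited_cds, delta_nt, codon_swaps, ins_payload)`` where
    ``codon_swaps`` are ``(wt_codon_index, old, new)`` records and
    ``ins_payload`` is the (possibly later-recoded) inserted sequence.
    """
    cds = design.gene.cds
    usage = design.usage
    p = variant.codon_pos
    c0 = 3 * (p - 1)
    construct5 = design.up_ctx + cds[:c0]
    construct3 = cds[3 * p :] + design.down_ctx
    if variant.kind in ("missense", "stop"):
        new = _choose_codon_or_least_bad(variant.payload, usage, construct5, construct3)
        ecds = cds[:c0] + new + cds[3 * p :]
        return ecds, 0, [(p, cds[c0 : c0 + 3], new)], ""
    if variant.kind == "synonymous":
        wt_codon = cds[c0 : c0 + 3]
        new = _choose_codon_or_least_bad(
            CODON_TO_AA[wt_codon], usage, construct5, construct3, exclude=[wt_codon]
        )
        ecds = cds[:c0] + new + cds[3 * p :]
        return ecds, 0, [(p, wt_codon, new)], ""
    if variant.kind == "insertion":
        ecds = cds[: 3 * p] + variant.payload + cds[3 * p :]
        return ecds, len(variant.payload), [], variant.payload
    if variant.kind == "deletion":
        k = variant.span
        ecds = cds[:c0] + cds[3 * (p - 1 + k) :]
        return ecds, -3 * k, [], ""
    raise ValueError(f"unknown variant kind {variant.kind!r}")


def _rescue_sites(
    design: Design,
    variant: VariantSpec,
    sub: Sublibrary,
    ecds: str,
    delta: int,
    swaps: list[tuple[int, str, str]],
    ins_payload: str,
) -> tuple[str, list[tuple[int, str, str]], str]:
    """Synonymously recode codons so the edited construct has no enzyme site.

    Edits can fuse sequence into a new recognition site (most often at
    deletion junctions). Any codon inside the mutable window of the edited
    frame may be swapped for a synonym, which leaves the protein-level
    intent untouched; swaps inside an inserted payload rewrite the payload.
    """
    enzymes = DEFAULT_ENZYMES  # keep both bundled enzymes out of every oligo
    usage = design.usage
    p, k = variant.codon_pos, variant.span
    ins_at = 3 * p if variant.kind == "insertion" else None
    n_ins = len(ins_payload) // 3

    start, end = design.fragment_span(sub)
    u = design.cds_offset

    def eligible(ci: int, tier: int) -> bool:
        """May the 1-based edited-frame codon ``ci`` be recoded?

        Tier 1 allows codons inside the sublibrary's mutable window
        (mapped back to wild-type coordinates through the indel) plus
        inserted payload codons. Tier 2 additionally allows wild-type
        flank codons inside the fragment, as long as they do not overlap
        either junction overhang — a last resort for edits at window
        boundaries whose new site reaches into the flank.
        """
        if variant.kind == "deletion":
            wt_ci = ci if ci < p else ci + k
        elif variant.kind == "insertion":
            if p < ci <= p + n_ins:
                return True  # payload codon, inside the window by placement
            wt_ci = ci if ci <= p else ci - n_ins
        else:
            wt_ci = ci
        if sub.codon_start <= wt_ci <= sub.codon_end:
            return True
        if tier < 2:
            return False
        oh = design.enzyme.overhang_len
        c_lo = u + 3 * (ci - 1)  # edited-construct nt span of the codon
        c_hi = c_lo + 3
        if not (start <= c_lo and c_hi <= end + delta):
            return False
        if c_lo < start + oh or c_hi > end + delta - oh:
            return False
        return True

    for _round in range(8):
        econstruct = design.up_ctx + ecds + design.down_ctx
        hits = scan_sites(econstruct, enzymes)
        if not hits:
            return ecds, swaps, ins_payload
        n_before = len(hits)
        enz, _strand, off = hits[0]
        site0 = off - 1 - design.cds_offset  # 0-based within edited CDS
        site1 = site0 + len(enz.recognition) - 1
        first_codon = max(site0 // 3, 0)
        last_codon = site1 // 3
        fixed = False
        for tier in (1, 2):
            for ci in range(first_codon, last_codon + 1):  # 0-based edited codon index
                if not eligible(ci + 1, tier):
                    continue
                if tier == 2 and eligible(ci + 1, 1):
                    continue  # already tried in tier 1
                old = ecds[3 * ci : 3 * ci + 3]
                if len(old) < 3:
                    continue
                # don't revert a synonymous variant's own codon to wild type
                forbidden = set()
                if variant.kind == "synonymous" and ci == p - 1:
                    forbidden.add(design.gene.codon(p))
                for alt in usage.synonyms(old):
                    if alt in forbidden:
                        continue
                    cand = ecds[: 3 * ci] + alt + ecds[3 * ci + 3 :]
                    cand_hits = scan_sites(design.up_ctx + cand + design.down_ctx, enzymes)
                    if len(cand_hits) < n_before:
                        ecds = cand
                        # map the edited codon index back to wild-type coordinates
                        if variant.kind == "deletion" and ci >= p - 1:
                            swaps = swaps + [(ci + k + 1, old, alt)]
                        elif ins_at is not None and 3 * ci >= ins_at:
                            if 3 * ci < ins_at + len(ins_payload):
                                j = 3 * ci - ins_at
                                ins_payload = ins_payload[:j] + alt + ins_payload[j + 3 :]
                            else:
                                swaps = swaps + [(ci + 1 - n_ins, old, alt)]
                        else:
                            swaps = swaps + [(ci + 1, old, alt)]
                        fixed = True
                        break
                if fixed:
                    break
            if fixed:
                break
        if not fixed:
            raise OligoBuildError(
                f"{variant.name}: cannot remove {enz.name} site created by the edit"
            )
    raise OligoBuildError(f"{variant.name}: site rescue did not converge")


def variant_signature(
    design: Design,
    variant: VariantSpec,
    swaps: Sequence[tuple[int, str, str]],
    ins_payload: str,
) -> str:
    """Canonical nucleotide-level genotype string, wild-type CDS coordinates."""
    ops: list[tuple[int, str]] = []
    # merge chained swaps at the same codon so refs are wild-type bases
    merged: dict[int, tuple[str, str]] = {}
    for ci, old, new in swaps:
        if ci in merged:
            merged[ci] = (merged[ci][0], new)
        else:
            merged[ci] = (old, new)
    for ci, (old, new) in merged.items():
        base = 3 * (ci - 1)
        for j in range(3):
            if old[j] != new[j]:
                ops.append((base + j + 1, f"{base + j + 1}{old[j]}>{new[j]}"))
    if variant.kind == "insertion":
        pos = 3 * variant.codon_pos
        ops.append((pos, f"{pos}_{pos + 1}ins{ins_payload}"))
    elif variant.kind == "deletion":
        start = 3 * (variant.codon_pos - 1) + 1
        end = 3 * (variant.codon_pos + variant.span - 1)
        ops.append((start, f"{start}_{end}del"))
    ops.sort()
    sig = ";".join(op for _pos, op in ops)
    assert sig, f"empty signature for {variant.name}"
    return sig


def build_oligo(
    variant: VariantSpec,
    sub: Sublibrary,
    design: Design,
    _primer_kmer_cache: set[str] | None = None,
) -> Oligo:
    """Assemble one synthesis-ready oligo for ``variant`` in ``sub``.

    All oligos of a sublibrary share one synthesis length (that of the
    longest-insertion variant); shorter payloads are compensated with
    vetted filler buffer split evenly 5'/3' (odd remainder to the 3' end).
    """
    geom, enzyme = design.geom, design.enzyme
    common_len = design.common_oligo_len(sub)
    if common_len > geom.max_oligo_len:
        raise OligoTooLong(
            f"sublibrary {sub.index}: common length {common_len} exceeds "
            f"{geom.max_oligo_len} nt"
        )
    ecds, delta, swaps, ins_payload = _apply_edit(design, variant)
    ecds, swaps, ins_payload = _rescue_sites(
        design, variant, sub, ecds, delta, swaps, ins_payload
    )
    econstruct = design.up_ctx + ecds + design.down_ctx
    start, end = design.fragment_span(sub)
    fragment = econstruct[start : end + delta]
    if fragment[: enzyme.overhang_len] != sub.up_overhang or fragment[-enzyme.overhang_len :] != sub.down_overhang:
        raise OligoBuildError(f"{variant.name}: edit corrupted a junction overhang")

    spacer5 = "A" * enzyme.spacer_len
    spacer3 = "T" * enzyme.spacer_len
    cassette5 = enzyme.recognition + spacer5
    cassette3 = spacer3 + reverse_complement(enzyme.recognition)
    core = cassette5 + fragment + cassette3
    fixed = 2 * geom.primer_len + len(core)
    buf_total = common_len - fixed
    if buf_total < 0:
        raise OligoTooLong(f"{variant.name}: zero-buffer length {fixed} exceeds common length")
    b5 = buf_total // 2
    b3 = buf_total - b5

    pool = _filler_pool(DEFAULT_ENZYMES)
    kmers = _primer_kmer_cache if _primer_kmer_cache is not None else _primer_kmers(design)
    fwd = sub.barcode_fwd
    rev = reverse_complement(sub.barcode_rev)
    offset = (131 * (sub.index - 1)) % 1000
    seq = ""
    for attempt in range(80):
        o = offset + attempt
        buf5 = pool[o : o + b5]
        buf3 = pool[o + b5 : o + b5 + b3]
        seq = fwd + buf5 + core + buf3 + rev
        # the finished oligo must contain the recognition sequence exactly
        # twice (once per cassette) and no primer-length filler cross-match
        n_sites = seq.count(enzyme.recognition) + seq.count(reverse_complement(enzyme.recognition))
        if n_sites != 2:
            continue
        other = BSMBI if enzyme.recognition == BSAI.recognition else BSAI
        if other.recognition in seq or reverse_complement(other.recognition) in seq:
            continue
        if kmers and any(
            buf[i : i + 12] in kmers for buf in (buf5, buf3) for i in range(max(len(buf) - 11, 0))
        ):
            continue
        break
    else:
        raise OligoBuildError(f"{variant.name}: no acceptable buffer filler found")

    # flank / payload breakdown for the layout record
    flank5_len = (design.cds_offset + 3 * (sub.codon_start - 1)) - start
    flank3_len = end - (design.cds_offset + 3 * sub.codon_end)
    if variant.kind == "deletion":
        intrusion = 3 * max(variant.codon_pos + variant.span - 1 - sub.codon_end, 0)
        flank3_len = max(flank3_len - intrusion, 0)
    payload_len = len(fragment) - flank5_len - flank3_len
    layout = (
        ("fwd_primer", len(fwd)),
        ("buffer5", b5),
        ("cassette5", len(cassette5)),
        ("flank5", flank5_len),
        ("payload", payload_len),
        ("flank3", flank3_len),
        ("cassette3", len(cassette3)),
        ("buffer3", b3),
        ("rev_primer", len(rev)),
    )
    assert sum(n for _, n in layout) == len(seq) == common_len
    return Oligo(
        variant_name=variant.name,
        sublibrary=sub.index,
        sequence=seq,
        layout=layout,
        signature=variant_signature(design, variant, swaps, ins_payload),
    )


# ---------------------------------------------------------------------------
# Primer design
# ---------------------------------------------------------------------------


def melting_tm(seq: str) -> float:
    """Nearest-neighbor Tm at 50 mM monovalent salt, 250 nM primer."""
    return float(_mt.Tm_NN(seq, Na=50, dnac1=250, dnac2=0))


def _suffix_identity(a: str, b: str) -> int:
    n = 0
    while n < min(len(a), len(b)) and a[-1 - n] == b[-1 - n]:
        n += 1
    return n


_BARCODE_CACHE: list[str] = []


def orthogonal_barcodes(
    n: int,
    length: int = 18,
    tm_threshold: float = 58.0,
    enzymes: Sequence[EnzymeProfile] = DEFAULT_ENZYMES,
) -> list[str]:
    """The bundled orthogonal subpool barcode set (first ``n`` members).

    Deterministically generated 18-mers screened for 40-60% GC, absence of
    enzyme recognition sites on either strand, pairwise 3'-end identity of
    at most 8 nt, and nearest-neighbor Tm at or above the threshold.
    """
    global _BARCODE_CACHE
    rng = np.random.default_rng(58230)
    bases = "ACGT"
    accepted = list(_BARCODE_CACHE)
    while len(accepted) < n:
        cand = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        gc = (cand.count("G") + cand.count("C")) / length
        if not 0.40 <= gc <= 0.60:
            continue
        if scan_sites(cand, enzymes):
            continue
        if melting_tm(cand) < tm_threshold:
            continue
        if any(
            _suffix_identity(cand, prev) > 8 or _suffix_identity(cand, reverse_complement(prev)) > 8
            for prev in accepted
        ):
            continue
        if cand in accepted:
            continue
        accepted.append(cand)
    if len(accepted) > len(_BARCODE_CACHE):
        _BARCODE_CACHE = list(accepted)
    return accepted[:n]


def design_primers(
    design: Design,
    tm_threshold: float = 58.0,
    max_anneal_len: int = 40,
) -> None:
    """Assign subpool barcode pairs and backbone inverse-PCR pairs, in place.

    Subpool pairs come from the bundled orthogonal barcode set (one unique
    pair per sublibrary). Each backbone pair anneals immediately outside
    the fragment and carries a 5' cassette tail so that digestion of the
    backbone amplicon exposes overhangs complementary to the fragment
    junctions; annealing regions are extended (up to ``max_anneal_len``)
    until their nearest-neighbor Tm reaches the threshold.
    """
    subs = design.sublibraries
    barcodes = orthogonal_barcodes(2 * len(subs), design.geom.primer_len, tm_threshold)
    construct = design.construct
    enzyme = design.enzyme
    pairs: list[PrimerPair] = []
    for i, sub in enumerate(subs):
        sub.barcode_fwd = barcodes[2 * i]
        sub.barcode_rev = barcodes[2 * i + 1]
        pairs.append(
            PrimerPair(
                kind="subpool",
                sublibrary=sub.index,
                fwd=sub.barcode_fwd,
                rev=sub.barcode_rev,
                fwd_anneal=sub.barcode_fwd,
                rev_anneal=sub.barcode_rev,
                fwd_tm=melting_tm(sub.barcode_fwd),
                rev_tm=melting_tm(sub.barcode_rev),
            )
        )
        start, end = design.fragment_span(sub)
        oh = enzyme.overhang_len
        tail = enzyme.recognition + "A" * enzyme.spacer_len

        def extend(anchor: int, direction: int) -> str:
            for alen in range(design.geom.primer_len, max_anneal_len + 1):
                if direction > 0:
                    region = construct[anchor : anchor + alen]
                else:
                    region = construct[anchor - alen : anchor]
                if len(region) < alen:
                    break
                if melting_tm(region) >= tm_threshold:
                    return region
            raise PrimerDesignFailure(
                f"sublibrary {sub.index}: no annealing region reaches "
                f"Tm {tm_threshold} within {max_anneal_len} nt"
            )

        fwd_anneal = extend(end - oh, +1)
        rev_anneal_top = extend(start + oh, -1)
        pairs.append(
            PrimerPair(
                kind="backbone",
                sublibrary=sub.index,
                fwd=tail + fwd_anneal,
                rev=tail + reverse_complement(rev_anneal_top),
                fwd_anneal=fwd_anneal,
                rev_anneal=reverse_complement(rev_anneal_top),
                fwd_tm=melting_tm(fwd_anneal),
                rev_tm=melting_tm(rev_anneal_top),
            )
        )
    names = [s.barcode_fwd for s in subs] + [s.barcode_rev for s in subs]
    assert len(set(names)) == len(names), "barcode uniqueness violated"
    design.primers = pairs


# ---------------------------------------------------------------------------
# Contexts and pipeline
# ---------------------------------------------------------------------------


def _default_contexts(
    cds: str,
    enzymes: Sequence[EnzymeProfile],
    length: int = 80,
) -> tuple[str, str]:
    """Deterministic linear backbone context free of enzyme sites."""
    rng = np.random.default_rng(40962)
    bases = "ACGT"
    for _ in range(200):
        up = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        down = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        construct = up + cds + down
        internal = [h for h in scan_sites(construct, enzymes)]
        cds_hits = scan_sites(cds, enzymes) if cds else []
        if len(internal) == len(cds_hits):
            return up, down
    raise DesignError("could not generate site-free backbone context")


def design_library(
    gene: TargetGene,
    geom: GeometryConfig | None = None,
    vcfg: VariantConfig | None = None,
    usage: CodonUsageTable | None = None,
    enzyme: EnzymeProfile = BSAI,
    up_ctx: str | None = None,
    down_ctx: str | None = None,
    tm_threshold: float = 58.0,
) -> Design:
    """Run the full design pipeline and return a complete :class:`Design`.

    Domesticates the gene, partitions it, assigns overhangs and primers,
    enumerates every variant, and builds all oligos. Variants whose oligo
    cannot be built are recorded in ``design.build_failures`` rather than
    aborting the run.
    """
    geom = geom or GeometryConfig()
    vcfg = vcfg or VariantConfig()
    usage = usage or CodonUsageTable.default()
    vcfg.validate_against(geom)
    dom_gene, edits = domesticate(gene, DEFAULT_ENZYMES, usage)
    if up_ctx is None or down_ctx is None:
        auto_up, auto_down = _default_contexts(dom_gene.cds, DEFAULT_ENZYMES)
        up_ctx = up_ctx if up_ctx is not None else auto_up
        down_ctx = down_ctx if down_ctx is not None else auto_down
    design = Design(
        gene=dom_gene,
        geom=geom,
        vcfg=vcfg,
        usage=usage,
        enzyme=enzyme,
        up_ctx=up_ctx,
        down_ctx=down_ctx,
        domestication_edits=edits,
    )
    design.sublibraries = partition_gene(dom_gene, geom, vcfg, enzyme)
    select_overhangs(design)
    design_primers(design, tm_threshold=tm_threshold)
    design.variants = enumerate_variants(dom_gene, vcfg, usage, geom)
    kmers = _primer_kmers(design)
    for variant in design.variants:
        sub = design.sublibrary_for(variant.codon_pos)
        try:
            design.oligos[variant.name] = build_oligo(variant, sub, design, kmers)
        except DesignError as exc:
            design.build_failures[variant.name] = str(exc)
    return design
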