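"""Golden Gate digestion/ligation simulation and end-to-end design audit.

Every designed oligo is digested in silico with the assembly enzyme,
ligated into its sublibrary's backbone amplicon (exact-complement overhang
matching only — Type IIS assembly relies on enzyme fidelity, and mismatch
ligation is not modeled), and the reconstructed full-length coding sequence
is translated and compared against the intended protein-level edit.
:func:`verify_design` aggregates this into a design-wide completeness and
in-frame report; a correct design yields an intent-match fraction of 1.0
and zero residual enzyme sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .design_core import Design, Oligo, Sublibrary, VariantSpec
from .sequence_model import (
    DEFAULT_ENZYMES,
    EnzymeProfile,
    reverse_complement,
    translate,
)

__all__ = [
    "Insert",
    "BackboneArms",
    "AssemblyProduct",
    "VerificationReport",
    "AssemblyError",
    "MissingSite",
    "WrongOrientation",
    "OverhangMismatch",
    "digest",
    "backbone_arms",
    "assemble",
    "expected_protein",
    "verify_design",
]


class AssemblyError(RuntimeError):
    pass


class MissingSite(AssemblyError):
    """The oligo lacks one or both enzyme cassettes."""


class WrongOrientation(AssemblyError):
    """The two cassettes do not cut convergently into the fragment."""


class OverhangMismatch(AssemblyError):
    """Insert and backbone overhangs are not exact reverse complements."""


@dataclass(frozen=True)
class Insert:
    """A digested fragment with its single-stranded 4-nt junction ends."""

    seq: str
    up_overhang: str
    down_overhang: str


@dataclass(frozen=True)
class BackboneArms:
    """The linearized backbone amplicon after digestion.

    ``left`` ends with the 4-nt overhang that pairs with the insert's 5'
    end; ``right`` starts with the overhang pairing with the insert's 3'
    end. Modeling the inverse-PCR amplicon as two linear arms around the
    excised fragment is sufficient for intent verification.
    """

    left: str
    right: str
    overhang_len: int = 4

    @property
    def left_overhang(self) -> str:
        return self.left[-self.overhang_len :]

    @property
    def right_overhang(self) -> str:
        return self.right[: self.overhang_len]


@dataclass(frozen=True)
class AssemblyProduct:
    variant_name: str
    full_cds: str
    in_frame: bool
    protein: str
    matches_intent: bool


@dataclass
class VerificationReport:
    designed: int = 0
    assembled: int = 0
    in_frame: int = 0
    intent_matched: int = 0
    residual_sites: int = 0
    failures: list[tuple[str, str]] = field(default_factory=list)
    per_sublibrary: dict[int, dict[str, int]] = field(default_factory=dict)

    @property
    def assembled_fraction(self) -> float:
        return self.assembled / self.designed if self.designed else 0.0

    @property
    def in_frame_fraction(self) -> float:
        return self.in_frame / self.designed if self.designed else 0.0

    @property
    def intent_match_fraction(self) -> float:
        return self.intent_matched / self.designed if self.designed else 0.0

    def to_dict(self) -> dict:
        return {
            "designed": self.designed,
            "assembled": self.assembled,
            "in_frame_fraction": self.in_frame_fraction,
            "intent_match_fraction": self.intent_match_fraction,
            "residual_enzyme_sites": self.residual_sites,
            "failures": self.failures,
            "per_sublibrary": self.per_sublibrary,
        }


def digest(oligo: Oligo | str, enzyme: EnzymeProfile) -> Insert:
    """Cut one oligo with its Type IIS enzyme and return the insert.

    The oligo must contain exactly one plus-strand and one minus-strand
    recognition site in convergent orientation (cutting toward each other).
    The returned insert carries the two single-stranded overhang 4-mers at
    its ends, located ``spacer_len`` nucleotides beyond each recognition
    sequence.
    """
    seq = oligo.sequence if isinstance(oligo, Oligo) else oligo
    rec = enzyme.recognition
    rc = reverse_complement(rec)
    plus = [i for i in range(len(seq)) if seq.startswith(rec, i)]
    minus = [i for i in range(len(seq)) if seq.startswith(rc, i)]
    if len(plus) != 1 or len(minus) != 1:
        raise MissingSite(
            f"expected one site per strand, found {len(plus)} plus / {len(minus)} minus"
        )
    p, m = plus[0], minus[0]
    cut5 = p + len(rec) + enzyme.spacer_len  # first base of the 5' overhang
    cut3 = m - enzyme.spacer_len  # one past the 3' overhang
    if cut5 >= cut3:
        raise WrongOrientation("cassettes do not cut convergently")
    insert = seq[cut5:cut3]
    if len(insert) < 2 * enzyme.overhang_len:
        raise WrongOrientation("insert shorter than its two overhangs")
    return Insert(insert, insert[: enzyme.overhang_len], insert[-enzyme.overhang_len :])


def backbone_arms(design: Design, sub: Sublibrary) -> BackboneArms:
    """The digested backbone amplicon for one sublibrary.

    Simulates inverse PCR with the sublibrary's backbone primer pair
    followed by digestion: the arms cover the whole construct outside the
    fragment, each retaining the wild-type junction overhang.
    """
    construct = design.construct
    start, end = design.fragment_span(sub)
    oh = design.enzyme.overhang_len
    return BackboneArms(
        left=construct[: start + oh],
        right=construct[end - oh :],
        overhang_len=oh,
    )


def assemble(insert: Insert, arms: BackboneArms, design: Design, variant: VariantSpec) -> AssemblyProduct:
    """Ligate an insert into backbone arms and audit the product.

    Ligation happens only when both overhang pairs match exactly; the
    product's CDS is re-extracted from the reconstructed construct,
    translated, and compared with the wild-type protein carrying exactly
    the intended edit.
    """
    if insert.up_overhang != arms.left_overhang or insert.down_overhang != arms.right_overhang:
        raise OverhangMismatch(
            f"{variant.name}: insert overhangs ({insert.up_overhang}, "
            f"{insert.down_overhang}) do not match backbone "
            f"({arms.left_overhang}, {arms.right_overhang})"
        )
    oh = arms.overhang_len
    product = arms.left + insert.seq[oh:] + arms.right[oh:]
    delta = len(product) - len(design.construct)
    u = design.cds_offset
    full_cds = product[u : u + len(design.gene.cds) + delta]
    in_frame = len(full_cds) % 3 == 0
    protein = translate(full_cds) if in_frame else ""
    expected = expected_protein(design.gene.protein, variant)
    return AssemblyProduct(
        variant_name=variant.name,
        full_cds=full_cds,
        in_frame=in_frame,
        protein=protein,
        matches_intent=in_frame and protein == expected,
    )


def expected_protein(wt_protein: str, variant: VariantSpec) -> str:
    """The wild-type protein with exactly the specified edit applied."""
    p = variant.codon_pos
    if variant.kind in ("missense", "stop"):
        return wt_protein[: p - 1] + variant.payload + wt_protein[p:]
    if variant.kind == "synonymous":
        return wt_protein
    if variant.kind == "insertion":
        return wt_protein[:p] + translate(variant.payload) + wt_protein[p:]
    if variant.kind == "deletion":
        return wt_protein[: p - 1] + wt_protein[p - 1 + variant.span :]
    raise ValueError(f"unknown variant kind {variant.kind!r}")


def verify_design(design: Design) -> VerificationReport:
    """Attempt every designed variant and aggregate the outcome.

    Assembly failures are counted and named, never raised. Residual sites
    are recognition occurrences (either strand, either bundled enzyme)
    beyond the two expected cassette sites of each oligo.
    """
    report = VerificationReport(designed=len(design.variants))
    arms_cache: dict[int, BackboneArms] = {}
    specs = {v.name: v for v in design.variants}
    for sub in design.sublibraries:
        report.per_sublibrary[sub.index] = {
            "designed": 0,
            "intent_matched": 0,
            "residual_sites": 0,
        }
    for name, variant in specs.items():
        sub = design.sublibrary_for(variant.codon_pos)
        row = report.per_sublibrary[sub.index]
        row["designed"] += 1
        oligo = design.oligos.get(name)
        if oligo is None:
            report.failures.append((name, design.build_failures.get(name, "not built")))
            continue
        n_sites = sum(
            oligo.sequence.count(pat)
            for e in DEFAULT_ENZYMES
            for pat in (e.recognition, reverse_complement(e.recognition))
        )
        extra = max(n_sites - 2, 0)
        report.residual_sites += extra
        row["residual_sites"] += extra
        try:
            insert = digest(oligo, design.enzyme)
            if sub.index not in arms_cache:
                arms_cache[sub.index] = backbone_arms(design, sub)
            product = assemble(insert, arms_cache[sub.index], design, variant)
        except AssemblyError as exc:
            report.failures.append((name, str(exc)))
            continue
        report.assembled += 1
        if product.in_frame:
            report.in_frame += 1
        if product.matches_intent:
            report.intent_matched += 1
            row["intent_matched"] += 1
        else:
            report.failures.append((name, "protein does not match intent"))
    return report
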