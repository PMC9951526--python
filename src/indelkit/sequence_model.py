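"""Target genes, Type IIS enzymes, codon usage, and CDS domestication.

This module holds the sequence-level foundations of the library designer:

* :class:`TargetGene` — a validated in-frame coding sequence plus the codon
  window that will be mutagenized.
* :class:`EnzymeProfile` — a Type IIS (Golden Gate) enzyme described by its
  recognition sequence, spacer, and overhang length.
* :class:`CodonUsageTable` — per-amino-acid relative codon frequencies used
  whenever a codon has to be chosen (synonymous swaps, missense payloads).
* :func:`scan_sites` / :func:`domesticate` — find recognition sites on both
  strands and remove internal sites by synonymous, usage-ranked codon swaps
  ("domestication"), a prerequisite for Golden Gate assembly.

Coordinates are 1-based throughout: codon indices are 1-based positions in
the protein, nucleotide offsets are 1-based and inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "CODON_TO_AA",
    "AA_TO_CODONS",
    "STANDARD_AAS",
    "translate",
    "reverse_complement",
    "EnzymeProfile",
    "BSAI",
    "BSMBI",
    "DEFAULT_ENZYMES",
    "CodonUsageTable",
    "TargetGene",
    "GeneValidationError",
    "UndomesticatableSite",
    "read_target",
    "scan_sites",
    "domesticate",
]

# ---------------------------------------------------------------------------
# Genetic code helpers
# ---------------------------------------------------------------------------

_standard = CodonTable.unambiguous_dna_by_name["Standard"]

#: codon -> one-letter amino acid ('*' for stop), standard genetic code
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: amino acid -> tuple of codons encoding it
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

#: the 20 standard amino acids, alphabetical one-letter order
STANDARD_AAS: str = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate an in-frame nucleotide string (standard code, '*' = stop)."""
    if len(cds) % 3:
        raise GeneValidationError(f"sequence length {len(cds)} is not a multiple of 3")
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))


class GeneValidationError(ValueError):
    """Raised when a coding sequence violates the TargetGene contract."""


class UndomesticatableSite(RuntimeError):
    """Raised when an internal recognition site cannot be removed synonymously."""


# ---------------------------------------------------------------------------
# Enzymes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnzymeProfile:
    """A Type IIS restriction enzyme.

    ``recognition`` is the top-strand recognition sequence; the enzyme cuts
    ``spacer_len`` nucleotides downstream of it, leaving a 5' overhang of
    ``overhang_len`` nucleotides. Type IIS recognition sequences are
    non-palindromic, so both strands must always be scanned.
    """

    name: str
    recognition: str
    spacer_len: int = 1
    overhang_len: int = 4

    def __post_init__(self) -> None:
        if self.overhang_len < 1:
            raise ValueError("overhang_len must be >= 1")
        if set(self.recognition) - set("ACGT"):
            raise ValueError("recognition must be uppercase ACGT")

    @property
    def cassette_len(self) -> int:
        """Recognition + spacer + overhang footprint on one oligo side."""
        return len(self.recognition) + self.spacer_len + self.overhang_len


BSAI = EnzymeProfile("BsaI", "GGTCTC", spacer_len=1, overhang_len=4)
BSMBI = EnzymeProfile("BsmBI", "CGTCTC", spacer_len=1, overhang_len=4)

#: enzymes removed from every designed gene by default
DEFAULT_ENZYMES: tuple[EnzymeProfile, ...] = (BSAI, BSMBI)


def scan_sites(
    seq: str, enzymes: Sequence[EnzymeProfile]
) -> list[tuple[EnzymeProfile, str, int]]:
    """Locate recognition sites on both strands.

    Returns ``(enzyme, strand, offset)`` tuples where ``strand`` is ``'+'``
    or ``'-'`` and ``offset`` is the 1-based position of the first
    top-strand base of the match. For a minus-strand site the match is the
    reverse complement of the recognition sequence as read on the top
    strand. Results are sorted by offset, then strand, then enzyme name.
    """
    if not seq:
        raise ValueError("empty sequence")
    hits: list[tuple[EnzymeProfile, str, int]] = []
    for enz in enzymes:
        for pattern, strand in ((enz.recognition, "+"), (reverse_complement(enz.recognition), "-")):
            start = seq.find(pattern)
            while start != -1:
                hits.append((enz, strand, start + 1))
                start = seq.find(pattern, start + 1)
    hits.sort(key=lambda h: (h[2], h[1], h[0].name))
    return hits


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative codon frequencies per amino acid.

    ``table`` maps one-letter amino acid (plus ``'*'``) to a tuple of
    ``(codon, fraction)`` sorted by descending fraction. Fractions for each
    amino acid sum to 1 (normalized on construction; input must already sum
    to 1 within 1e-3 or a warning is emitted).
    """

    table_id: str
    table: dict[str, tuple[tuple[str, float], ...]] = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(STANDARD_AAS) - set(self.table)
        if missing:
            raise ValueError(f"usage table lacks amino acids: {sorted(missing)}")
        for aa, rows in self.table.items():
            total = sum(f for _, f in rows)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"frequencies for {aa} sum to {total}, not 1")

    @classmethod
    def from_records(
        cls, table_id: str, records: Iterable[tuple[str, str, float]]
    ) -> "CodonUsageTable":
        raw: dict[str, list[tuple[str, float]]] = {}
        for aa, codon, frac in records:
            codon = codon.upper()
            if CODON_TO_AA.get(codon) != aa:
                raise ValueError(f"codon {codon} does not encode {aa}")
            raw.setdefault(aa, []).append((codon, float(frac)))
        norm: dict[str, tuple[tuple[str, float], ...]] = {}
        for aa, rows in raw.items():
            total = sum(f for _, f in rows)
            if total <= 0:
                raise ValueError(f"non-positive total frequency for {aa}")
            if abs(total - 1.0) > 1e-3:
                warnings.warn(f"frequencies for {aa} sum to {total:.4f}; normalizing")
            rows = [(c, f / total) for c, f in rows]
            rows.sort(key=lambda r: (-r[1], r[0]))
            norm[aa] = tuple(rows)
        return cls(table_id, norm)

    @classmethod
    def from_tsv(cls, path: str | Path, table_id: str | None = None) -> "CodonUsageTable":
        """Read a three-column TSV: amino acid, codon, relative fraction."""
        path = Path(path)
        records = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            aa, codon, frac = line.split("\t")
            records.append((aa, codon, float(frac)))
        return cls.from_records(table_id or path.stem, records)

    @classmethod
    def default(cls) -> "CodonUsageTable":
        """The bundled human high-frequency table."""
        global _DEFAULT_USAGE
        if _DEFAULT_USAGE is None:
            with resources.as_file(
                resources.files("indelkit.data") / "human_codon_usage.tsv"
            ) as p:
                _DEFAULT_USAGE = cls.from_tsv(p, table_id="human")
        return _DEFAULT_USAGE

    def codons_for(self, aa: str) -> tuple[tuple[str, float], ...]:
        """Codons for ``aa``, highest frequency first."""
        return self.table[aa]

    def top_codon(self, aa: str) -> str:
        return self.table[aa][0][0]

    def synonyms(self, codon: str) -> tuple[str, ...]:
        """Other codons encoding the same amino acid, by descending usage."""
        aa = CODON_TO_AA[codon.upper()]
        return tuple(c for c, _ in self.table[aa] if c != codon.upper())


_DEFAULT_USAGE: CodonUsageTable | None = None


# ---------------------------------------------------------------------------
# Target gene
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetGene:
    """A validated in-frame CDS and its mutagenesis window.

    ``mut_start``/``mut_end`` are 1-based inclusive codon indices into
    ``protein``. The protein includes a trailing ``'*'`` when the CDS ends
    with a stop codon; the mutagenesis window never includes that stop.
    """

    name: str
    cds: str
    protein: str
    mut_start: int
    mut_end: int
    usage_table_id: str = "human"

    def __post_init__(self) -> None:
        if set(self.cds) - set("ACGT"):
            raise GeneValidationError(f"{self.name}: CDS contains non-ACGT characters")
        if len(self.cds) % 3:
            raise GeneValidationError(
                f"{self.name}: CDS length {len(self.cds)} is not a multiple of 3"
            )
        if translate(self.cds) != self.protein:
            raise GeneValidationError(f"{self.name}: protein does not match CDS translation")
        if "*" in self.protein[:-1]:
            pos = self.protein.index("*") + 1
            raise GeneValidationError(f"{self.name}: internal stop codon at codon {pos}")
        if not (1 <= self.mut_start <= self.mut_end <= len(self.protein)):
            raise GeneValidationError(
                f"{self.name}: invalid mutagenesis window "
                f"{self.mut_start}..{self.mut_end} for {len(self.protein)} codons"
            )

    @property
    def n_codons(self) -> int:
        """Number of codons in the CDS (including a terminal stop, if any)."""
        return len(self.protein)

    @property
    def n_residues(self) -> int:
        """Number of amino acid residues (terminal stop excluded)."""
        return len(self.protein) - (1 if self.protein.endswith("*") else 0)

    @property
    def window_codons(self) -> int:
        return self.mut_end - self.mut_start + 1

    def codon(self, index: int) -> str:
        """The 1-based ``index``-th codon."""
        return self.cds[3 * (index - 1) : 3 * index]

    def with_cds(self, cds: str) -> "TargetGene":
        return replace(self, cds=cds, protein=translate(cds))


def make_target_gene(
    name: str,
    cds: str,
    window: tuple[int, int] | None = None,
    usage_table_id: str = "human",
) -> TargetGene:
    """Validate a CDS and construct a :class:`TargetGene`.

    The default mutagenesis window spans every residue, excluding a
    terminal stop codon when present.
    """
    cds = cds.upper()
    if set(cds) - set("ACGT"):
        raise GeneValidationError(f"{name}: CDS contains non-ACGT characters")
    protein = translate(cds)
    n_res = len(protein) - (1 if protein.endswith("*") else 0)
    if n_res < 1:
        raise GeneValidationError(f"{name}: no coding residues")
    if window is None:
        window = (1, n_res)
    return TargetGene(name, cds, protein, window[0], window[1], usage_table_id)


def read_target(
    path: str | Path,
    window: tuple[int, int] | None = None,
    fmt: str | None = None,
) -> TargetGene:
    """Load a target gene from a FASTA or GenBank file.

    The format is inferred from the extension unless ``fmt`` is given. For
    GenBank records the first CDS feature is used when present (falling
    back to the whole record sequence). ``window`` is an optional 1-based
    inclusive codon range; the default covers the full protein.
    """
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "fasta"
    record = next(SeqIO.parse(str(path), fmt))
    seq = str(record.seq).upper()
    if fmt == "genbank":
        cds_features = [f for f in record.features if f.type == "CDS"]
        if cds_features:
            seq = str(cds_features[0].extract(record.seq)).upper()
    return make_target_gene(record.id or path.stem, seq, window=window)


# ---------------------------------------------------------------------------
# Domestication
# ---------------------------------------------------------------------------


def _codons_overlapping(site_start: int, site_len: int, n_codons: int) -> list[int]:
    """1-based codon indices overlapping nucleotides [site_start, site_start+site_len-1]."""
    first = (site_start - 1) // 3 + 1
    last = (site_start + site_len - 2) // 3 + 1
    return [c for c in range(first, last + 1) if 1 <= c <= n_codons]


def domesticate(
    gene: TargetGene,
    enzymes: Sequence[EnzymeProfile] = DEFAULT_ENZYMES,
    usage: CodonUsageTable | None = None,
) -> tuple[TargetGene, list[tuple[int, str, str]]]:
    """Remove internal Type IIS recognition sites by synonymous codon swaps.

    Sites are processed 5'->3'; codons overlapping a site are tried left to
    right, and within a codon synonymous alternatives are tried in
    descending usage frequency. A swap is accepted if it strictly reduces
    the total site count (i.e. destroys the site without creating another).
    Returns the domesticated gene and the list of ``(codon_index, old_codon,
    new_codon)`` edits. The protein is unchanged by construction.

    Raises :class:`UndomesticatableSite` when a site overlaps only
    single-codon amino acids (Met/Trp) or every synonymous swap re-creates
    a site.
    """
    usage = usage or CodonUsageTable.default()
    cds = gene.cds
    n = len(cds) // 3
    edits: list[tuple[int, str, str]] = []

    while True:
        hits = scan_sites(cds, enzymes)
        if not hits:
            break
        n_before = len(hits)
        enz, strand, off = hits[0]
        site_len = len(enz.recognition)
        fixed = False
        for ci in _codons_overlapping(off, site_len, n):
            old = cds[3 * (ci - 1) : 3 * ci]
            for alt in usage.synonyms(old):
                cand = cds[: 3 * (ci - 1)] + alt + cds[3 * ci :]
                if len(scan_sites_or_empty(cand, enzymes)) < n_before:
                    cds = cand
                    edits.append((ci, old, alt))
                    fixed = True
                    break
            if fixed:
                break
        if not fixed:
            raise UndomesticatableSite(
                f"{gene.name}: cannot remove {enz.name} site at nt {off} ({strand}) "
                "by synonymous substitution"
            )

    return gene.with_cds(cds), edits


def scan_sites_or_empty(seq: str, enzymes: Sequence[EnzymeProfile]):
    """scan_sites variant returning [] for the empty string (internal helper)."""
    return scan_sites(seq, enzymes) if seq else []
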