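"""kdr genotyping and coding-sequence comparison.

Detects nucleotide differences between strain coding sequences of the
voltage-gated sodium channel, classifies them as synonymous or nonsynonymous,
calls diploid codon genotypes at the knockdown-resistance (kdr) positions 410
(V -> L, GTA -> TTA) and 1534 (F -> C, TTC -> TGC) from Sanger-style consensus
amplicons with IUPAC heterozygote codes, computes mutant allele frequencies,
and summarizes population screens.

Residue numbers are mapped through a per-sequence offset (reported residue =
sequence codon index + offset, both 1-based codon counting) because published
kdr positions are numbered against a reference channel protein.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "CodingSequence",
    "Difference",
    "VariantComparison",
    "CodonCall",
    "AlleleFrequencyResult",
    "ScreenSummary",
    "KDR_SITES",
    "IUPAC_CODES",
    "translate",
    "compare_cds",
    "call_codon",
    "allele_frequency",
    "screen_populations",
]

#: wild-type and mutant amino acid at the two kdr positions
KDR_SITES = {410: ("V", "L"), 1534: ("F", "C")}

#: IUPAC nucleotide codes expanded to base sets
IUPAC_CODES = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: base set -> single IUPAC letter (inverse of IUPAC_CODES)
IUPAC_FROM_BASES = {bases: code for code, bases in IUPAC_CODES.items()}

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


@dataclass(frozen=True)
class CodingSequence:
    """A coding nucleotide sequence with a residue-numbering offset."""

    id: str
    seq: str
    offset: int = 0

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())

    def codon(self, residue: int) -> str:
        """Codon string for a reported residue number (1-based)."""
        idx = residue - self.offset
        if idx < 1 or idx * 3 > len(self.seq):
            raise IndexError(
                f"residue {residue} (codon {idx}) outside sequence of "
                f"{len(self.seq) // 3} codons"
            )
        return self.seq[(idx - 1) * 3 : idx * 3]


def translate(cds) -> str:
    """Standard-genetic-code translation of an unambiguous CDS.

    Accepts a :class:`CodingSequence` or a plain string.  Ambiguity codes are
    rejected (translation is for unambiguous consensus sequences only) and
    internal stop codons raise a warning.
    """
    seq = cds.seq if isinstance(cds, CodingSequence) else str(cds).upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not divisible by 3")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(
            f"ambiguous or invalid bases {sorted(bad)}: full-CDS translation "
            "requires an unambiguous sequence"
        )
    protein = str(Seq(seq).translate())
    if "*" in protein[:-1]:
        warnings.warn("internal stop codon in coding sequence", stacklevel=2)
    return protein


@dataclass(frozen=True)
class Difference:
    position: int  # 1-based nucleotide position
    base_a: str
    base_b: str
    codon_number: int  # reported residue number (offset applied)
    aa_a: str
    aa_b: str
    klass: str  # "synonymous" | "nonsynonymous"


@dataclass(frozen=True)
class VariantComparison:
    differences: tuple

    @property
    def n_differences(self) -> int:
        return len(self.differences)

    @property
    def n_synonymous(self) -> int:
        return sum(d.klass == "synonymous" for d in self.differences)

    @property
    def n_nonsynonymous(self) -> int:
        return sum(d.klass == "nonsynonymous" for d in self.differences)

    @property
    def nonsynonymous(self) -> tuple:
        return tuple(d for d in self.differences if d.klass == "nonsynonymous")


def compare_cds(a: CodingSequence, b: CodingSequence) -> VariantComparison:
    """Positional comparison of two equal-length, equally numbered CDSs.

    Every mismatching nucleotide is reported with its codon context and
    synonymous/nonsynonymous class.  Sequences of unequal length are rejected:
    align them first, this module does no alignment.
    """
    if len(a.seq) != len(b.seq):
        raise ValueError(
            f"sequences differ in length ({len(a.seq)} vs {len(b.seq)}); "
            "pre-align them before comparison"
        )
    if a.offset != b.offset:
        raise ValueError("sequences have different residue-numbering offsets")
    diffs = []
    for pos0, (x, y) in enumerate(zip(a.seq, b.seq)):
        if x == y:
            continue
        codon_idx = pos0 // 3  # 0-based
        ca = a.seq[codon_idx * 3 : codon_idx * 3 + 3]
        cb = b.seq[codon_idx * 3 : codon_idx * 3 + 3]
        aa_a = _CODON_TABLE[ca]
        aa_b = _CODON_TABLE[cb]
        diffs.append(
            Difference(
                position=pos0 + 1,
                base_a=x,
                base_b=y,
                codon_number=codon_idx + 1 + a.offset,
                aa_a=aa_a,
                aa_b=aa_b,
                klass="synonymous" if aa_a == aa_b else "nonsynonymous",
            )
        )
    return VariantComparison(differences=tuple(diffs))


@dataclass(frozen=True)
class CodonCall:
    individual_id: str
    residue: int
    codon: str
    amino_acids: tuple
    zygosity: str  # hom_wild | het | hom_mutant | hom_other | ambiguous


def _expand_codon(codon: str):
    sets = []
    for base in codon.upper():
        if base not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC base {base!r} in codon {codon!r}")
        sets.append(sorted(IUPAC_CODES[base]))
    return sorted("".join(c) for c in itertools.product(*sets))


def call_codon(
    amplicon: str,
    residue: int,
    offset: int = 0,
    wild_aa: str | None = None,
    mutant_aa: str | None = None,
    individual_id: str = "",
) -> CodonCall:
    """Diploid genotype call at a residue from an IUPAC consensus amplicon.

    The codon string is expanded through its ambiguity codes: one expansion is
    a homozygote, two expansions a heterozygote, more than two cannot be a
    diploid consensus and is called ambiguous.  ``wild_aa``/``mutant_aa``
    default to the kdr key for residues 410 and 1534.
    """
    if wild_aa is None and residue in KDR_SITES:
        wild_aa, mutant_aa = KDR_SITES[residue]
    seq = amplicon.seq if isinstance(amplicon, CodingSequence) else str(amplicon).upper()
    idx = residue - offset
    if idx < 1 or idx * 3 > len(seq):
        raise IndexError(f"residue {residue} outside amplicon ({len(seq) // 3} codons)")
    codon = seq[(idx - 1) * 3 : idx * 3]
    expansions = _expand_codon(codon)
    aas = tuple(sorted({_CODON_TABLE[c] for c in expansions}))
    if len(expansions) > 2:
        zygosity = "ambiguous"
    elif len(expansions) == 2:
        zygosity = "het"
    else:
        aa = aas[0]
        if wild_aa is not None and aa == wild_aa:
            zygosity = "hom_wild"
        elif mutant_aa is not None and aa == mutant_aa:
            zygosity = "hom_mutant"
        else:
            zygosity = "hom_other"
    return CodonCall(
        individual_id=individual_id,
        residue=residue,
        codon=codon,
        amino_acids=aas,
        zygosity=zygosity,
    )


@dataclass(frozen=True)
class AlleleFrequencyResult:
    percent: float
    n_used: int
    n_excluded: int

    def __float__(self):
        return self.percent


def allele_frequency(panel, residue: int, mutant_aa: str | None = None) -> AlleleFrequencyResult:
    """Mutant allele frequency (%) at a residue over a genotype panel.

    ``panel`` maps individual id -> amplicon sequence (IUPAC consensus), or is
    a :class:`kdrkit.synthgen.GenotypePanel`.  Homozygous mutants contribute 2
    alleles, heterozygotes 1; ambiguous calls are excluded with a warning.
    """
    offset = getattr(panel, "offset", 0)
    individuals = getattr(panel, "individuals", panel)
    sites = getattr(panel, "sites", None)
    if mutant_aa is None:
        if sites is not None and residue in sites:
            mutant_aa = _CODON_TABLE[sites[residue][1]]
        elif residue in KDR_SITES:
            mutant_aa = KDR_SITES[residue][1]
        else:
            raise ValueError(f"mutant amino acid unknown for residue {residue}")
    count = 0
    n_used = 0
    n_excluded = 0
    for ind_id, seq in individuals.items():
        call = call_codon(seq, residue, offset=offset, mutant_aa=mutant_aa, individual_id=ind_id)
        if call.zygosity == "ambiguous":
            n_excluded += 1
            continue
        n_used += 1
        if call.zygosity == "hom_mutant":
            count += 2
        elif call.zygosity == "het" and mutant_aa in call.amino_acids:
            count += 1
    if n_excluded:
        warnings.warn(
            f"{n_excluded} ambiguous call(s) at residue {residue} excluded; "
            f"frequency computed over n={n_used}",
            stacklevel=2,
        )
    if n_used == 0:
        raise ValueError(f"no usable calls at residue {residue}")
    return AlleleFrequencyResult(
        percent=100.0 * count / (2 * n_used), n_used=n_used, n_excluded=n_excluded
    )


@dataclass(frozen=True)
class ScreenSummary:
    """Per-mutation carrier counts across screened populations."""

    carriers: dict  # residue -> tuple of population names carrying the mutant
    counts: dict  # residue -> carrier count
    n_populations: int
    flagged: tuple  # populations with invalid codon strings, excluded


def screen_populations(table, sites: dict | None = None) -> ScreenSummary:
    """Summarize a population screen of per-population codon strings.

    ``table`` maps population name -> {residue: codon string}; ``sites`` maps
    residue -> (wild codon, mutant codon), defaulting to the kdr key
    (410: GTA/TTA, 1534: TTC/TGC).  A population counts as a carrier at a site
    when any IUPAC expansion of its codon translates to the mutant amino acid
    (population rows report presence, not zygosity).  Populations with an
    invalid codon string are flagged and excluded from the totals.
    """
    if sites is None:
        sites = {410: ("GTA", "TTA"), 1534: ("TTC", "TGC")}
    mutant_aa = {res: _CODON_TABLE[mut] for res, (_, mut) in sites.items()}
    carriers = {res: [] for res in sites}
    flagged = []
    n_ok = 0
    for pop, codons in table.items():
        try:
            found = {}
            for res in sites:
                codon = codons[res]
                aas = {_CODON_TABLE[c] for c in _expand_codon(codon)}
                found[res] = mutant_aa[res] in aas
        except (ValueError, KeyError):
            flagged.append(pop)
            continue
        n_ok += 1
        for res, hit in found.items():
            if hit:
                carriers[res].append(pop)
    return ScreenSummary(
        carriers={res: tuple(v) for res, v in carriers.items()},
        counts={res: len(v) for res, v in carriers.items()},
        n_populations=n_ok,
        flagged=tuple(flagged),
    )
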