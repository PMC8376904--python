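"""NNK substrate library enumeration and lentiviral infection statistics.

A kinase FRET biosensor library randomizes three residues of the substrate
peptide flanking the consensus tyrosine with an NNK degenerate codon scheme
(N = A/C/G/T, K = G/T).  Three NNK codons give 32**3 = 32,768 DNA variants
covering 20**3 = 8,000 stop-free tripeptides plus variants carrying the
amber stop TAG.  Cells receive variants by lentiviral infection at low MOI
so that almost every infected cell carries a single variant; the Poisson
occupancy arithmetic for that design choice lives here too.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord
from scipy import stats

NNK_FIRST = "ACGT"
NNK_SECOND = "ACGT"
NNK_THIRD = "GT"
STOP_SYMBOL = "*"
AA20 = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "LibraryLayout",
    "SubstrateVariant",
    "InfectionProfile",
    "enumerate_nnk_codons",
    "enumerate_substrate_library",
    "translate_variant",
    "assemble_substrate",
    "poisson_infection_profile",
    "write_library_fasta",
    "fyn_lib2_layout",
    "zap70_lib2_layout",
    "layout_from_dict",
    "layout_from_yaml",
    "builtin_layout",
    "NNK_CODON_TABLE",
    "codons_for_aa",
]


def enumerate_nnk_codons() -> set[str]:
    """All 32 NNK codons: any base at positions 1-2, G or T at position 3."""
    return {
        a + b + c
        for a in NNK_FIRST
        for b in NNK_SECOND
        for c in NNK_THIRD
    }


def translate_variant(dna: str) -> str:
    """Translate a DNA string with the standard genetic code; stops become '*'.

    Raises ValueError for a length not divisible by 3 or for any base
    outside A/C/G/T (ambiguity codes are not valid library sequence).
    """
    if len(dna) % 3 != 0:
        raise ValueError(f"DNA length {len(dna)} is not a multiple of 3")
    if any(b not in "ACGT" for b in dna):
        raise ValueError(f"non-ACGT base in {dna!r}")
    return str(Seq(dna).translate())


#: codon -> residue for the 32 NNK codons (standard genetic code).
NNK_CODON_TABLE: dict[str, str] = {
    codon: translate_variant(codon) for codon in sorted(enumerate_nnk_codons())
}


def codons_for_aa(aa: str) -> list[str]:
    """NNK codons encoding a single residue (or '*'), sorted for determinism."""
    return sorted(c for c, r in NNK_CODON_TABLE.items() if r == aa)


@dataclass(frozen=True)
class LibraryLayout:
    """Geometry of one substrate library and its sequencing amplicon.

    The 50-bp single-end read is modeled as
    ``upstream_flank_dna + <variable region> + downstream_flank_dna``.
    The consensus tyrosine is encoded as a TAC codon inside one of the
    constant flanks; its read offset is derived from the residue spacing
    between ``tyrosine_position`` and the variable positions.

    Parameters
    ----------
    template_substrate : str
        Parental substrate peptide, e.g. ``"EKIEGTYGVV"``.
    variable_positions : tuple of int
        0-based residue indices randomized by the NNK primers; must be
        contiguous and exclude the tyrosine.
    tyrosine_position : int
        0-based index of the consensus tyrosine in the template.
    upstream_flank_dna, downstream_flank_dna : str
        Constant read sequence on either side of the variable region
        (vector/adapter bases plus the constant substrate codons).
    """

    template_substrate: str
    variable_positions: tuple[int, ...]
    tyrosine_position: int
    upstream_flank_dna: str
    downstream_flank_dna: str
    variable_region_length_nt: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        vp = tuple(sorted(int(i) for i in self.variable_positions))
        object.__setattr__(self, "variable_positions", vp)
        if not vp:
            raise ValueError("variable_positions must be non-empty")
        if vp != tuple(range(vp[0], vp[-1] + 1)):
            raise ValueError("variable_positions must be contiguous")
        if self.tyrosine_position in vp:
            raise ValueError("tyrosine_position cannot be variable")
        if not (0 <= self.tyrosine_position < len(self.template_substrate)):
            raise ValueError("tyrosine_position outside template")
        if self.template_substrate[self.tyrosine_position] != "Y":
            raise ValueError("template residue at tyrosine_position is not Y")
        if any(i < 0 or i >= len(self.template_substrate) for i in vp):
            raise ValueError("variable position outside template")
        expected_nt = 3 * len(vp)
        if self.variable_region_length_nt == 0:
            object.__setattr__(self, "variable_region_length_nt", expected_nt)
        elif self.variable_region_length_nt != expected_nt:
            raise ValueError(
                "variable_region_length_nt inconsistent with variable_positions"
            )
        for flank in (self.upstream_flank_dna, self.downstream_flank_dna):
            if any(b not in "ACGT" for b in flank):
                raise ValueError("flanks must be unambiguous A/C/G/T sequence")
        # Locate the TAC codon of the consensus tyrosine within the read.
        if self.tyrosine_position < vp[0]:
            gap_res = vp[0] - self.tyrosine_position - 1
            tyr_off = len(self.upstream_flank_dna) - 3 * (gap_res + 1)
        else:
            gap_res = self.tyrosine_position - vp[-1] - 1
            tyr_off = (
                len(self.upstream_flank_dna)
                + self.variable_region_length_nt
                + 3 * gap_res
            )
        if tyr_off < 0 or tyr_off + 3 > self.read_length:
            raise ValueError("tyrosine codon falls outside the read")
        object.__setattr__(self, "_tyr_offset", tyr_off)
        if self.constant_read_template()[tyr_off:tyr_off + 3] != "TAC":
            raise ValueError("flank sequence does not read TAC at the tyrosine codon")

    # -- derived read geometry -------------------------------------------------

    @property
    def read_length(self) -> int:
        return (
            len(self.upstream_flank_dna)
            + self.variable_region_length_nt
            + len(self.downstream_flank_dna)
        )

    @property
    def variable_offset(self) -> int:
        return len(self.upstream_flank_dna)

    @property
    def variable_slice(self) -> slice:
        return slice(
            self.variable_offset,
            self.variable_offset + self.variable_region_length_nt,
        )

    @property
    def tyrosine_codon_slice(self) -> slice:
        off: int = getattr(self, "_tyr_offset")
        return slice(off, off + 3)

    def constant_read_template(self, fill: str = "N") -> str:
        """The full read with the variable region replaced by ``fill``."""
        return (
            self.upstream_flank_dna
            + fill * self.variable_region_length_nt
            + self.downstream_flank_dna
        )

    def constant_positions(self) -> np.ndarray:
        """Read positions outside the variable region, tyrosine codon excluded."""
        tyr = set(range(*self.tyrosine_codon_slice.indices(self.read_length)))
        var = set(range(*self.variable_slice.indices(self.read_length)))
        return np.array(
            [i for i in range(self.read_length) if i not in var and i not in tyr],
            dtype=np.intp,
        )

    def scored_positions(self) -> np.ndarray:
        """All quality-scored positions: constant flanks plus the TAC codon."""
        var = set(range(*self.variable_slice.indices(self.read_length)))
        return np.array(
            [i for i in range(self.read_length) if i not in var], dtype=np.intp
        )

    def read_for_variant(self, variable_dna: str) -> str:
        if len(variable_dna) != self.variable_region_length_nt:
            raise ValueError("variable region length mismatch")
        return self.upstream_flank_dna + variable_dna + self.downstream_flank_dna

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "template_substrate": self.template_substrate,
            "variable_positions": list(self.variable_positions),
            "tyrosine_position": self.tyrosine_position,
            "upstream_flank_dna": self.upstream_flank_dna,
            "downstream_flank_dna": self.downstream_flank_dna,
            "variable_region_length_nt": self.variable_region_length_nt,
        }


@dataclass(frozen=True)
class SubstrateVariant:
    """One library member at DNA and amino-acid level.

    ``full_substrate`` is only assembled for stop-free variants; a variant
    carrying the amber stop has no meaningful peptide product.
    """

    dna: str
    aa: str
    contains_stop: bool
    full_substrate: str | None = None

    @classmethod
    def from_dna(cls, dna: str, layout: LibraryLayout | None = None) -> "SubstrateVariant":
        aa = translate_variant(dna)
        contains_stop = STOP_SYMBOL in aa
        full = None
        if layout is not None and not contains_stop:
            if len(aa) == len(layout.variable_positions):
                full = assemble_substrate(layout, aa)
        return cls(dna=dna, aa=aa, contains_stop=contains_stop, full_substrate=full)


def assemble_substrate(layout: LibraryLayout, variable_aa: str) -> str:
    """Insert randomized residues into the template at the variable positions."""
    if len(variable_aa) != len(layout.variable_positions):
        raise ValueError(
            f"expected {len(layout.variable_positions)} residues, got {len(variable_aa)}"
        )
    residues = list(layout.template_substrate)
    for pos, aa in zip(layout.variable_positions, variable_aa):
        residues[pos] = aa
    return "".join(residues)


def enumerate_substrate_library(
    n_positions: int, layout: LibraryLayout | None = None
) -> list[SubstrateVariant]:
    """Enumerate every NNK^n DNA variant with its translation.

    Returns 32**n_positions variants in lexicographic DNA order.  For three
    positions this is the full 32,768-member library whose stop-free
    translations cover the 8,000 possible tripeptides.
    """
    if n_positions <= 0:
        raise ValueError("n_positions must be >= 1")
    codons = sorted(enumerate_nnk_codons())
    variants = []
    for combo in itertools.product(codons, repeat=n_positions):
        dna = "".join(combo)
        aa = "".join(NNK_CODON_TABLE[c] for c in combo)
        contains_stop = STOP_SYMBOL in aa
        full = None
        if layout is not None and not contains_stop and len(aa) == len(layout.variable_positions):
            full = assemble_substrate(layout, aa)
        variants.append(
            SubstrateVariant(dna=dna, aa=aa, contains_stop=contains_stop, full_substrate=full)
        )
    return variants


def write_library_fasta(variants: Iterable[SubstrateVariant], path: str | Path) -> int:
    """Export a library as FASTA (id = DNA variant, description = peptide)."""
    records = [
        SeqRecord(Seq(v.dna), id=v.dna, description=v.aa) for v in variants
    ]
    with open(path, "w") as handle:
        return seqio_write(records, handle, "fasta")


@dataclass(frozen=True)
class InfectionProfile:
    """Poisson occupancy of viral integrations per cell at a given MOI."""

    moi: float
    p_zero: float
    p_one: float
    p_multi: float
    single_fraction_among_infected: float


def poisson_infection_profile(moi: float) -> InfectionProfile:
    """Poisson single-variant occupancy for lentiviral infection at ``moi``.

    With integrations per cell ~ Poisson(moi): p_zero = e^-moi uninfected,
    p_one = moi e^-moi single-variant, and everything else multi-variant.
    At the standard moi = 0.1 about 95% of infected (sorted) cells carry a
    single variant, which is what makes read counts attributable to one
    substrate sequence.
    """
    if not moi > 0:
        raise ValueError("moi must be positive")
    dist = stats.poisson(moi)
    p_zero = float(dist.pmf(0))
    p_one = float(dist.pmf(1))
    p_multi = float(dist.sf(1))
    return InfectionProfile(
        moi=float(moi),
        p_zero=p_zero,
        p_one=p_one,
        p_multi=p_multi,
        single_fraction_among_infected=p_one / (1.0 - p_zero),
    )


# -- layouts -------------------------------------------------------------------


def fyn_lib2_layout() -> LibraryLayout:
    """Fyn substrate library randomizing residues +1..+3 after the tyrosine.

    Template EKIEGTYGVV (p34cdc2-derived Fyn substrate); the read carries an
    8-nt vector stub, the 21 nt encoding EKIEGTY (ending in the TAC codon),
    the 9-nt NNK region replacing GVV, and a 12-nt downstream stub: 50 bp.
    """
    return LibraryLayout(
        name="fyn_lib2",
        template_substrate="EKIEGTYGVV",
        variable_positions=(7, 8, 9),
        tyrosine_position=6,
        upstream_flank_dna="ACTGGAGC" + "GAGAAGATCGAAGGCACCTAC",
        downstream_flank_dna="GGTGGATCCGAG",
    )


def zap70_lib2_layout() -> LibraryLayout:
    """ZAP70 substrate library randomizing residues +1..+3 after the tyrosine.

    Template SREYVNVSGEL (LAT Y191-derived ZAP70 substrate); the variable
    region replaces VNV directly after the TAC codon.
    """
    return LibraryLayout(
        name="zap70_lib2",
        template_substrate="SREYVNVSGEL",
        variable_positions=(4, 5, 6),
        tyrosine_position=3,
        upstream_flank_dna="ACTGGAGCA" + "TCCCGGGAATAC",
        downstream_flank_dna="AGCGGCGAGCTG" + "GGTGGATC",
    )


_BUILTIN_LAYOUTS = {
    "fyn_lib2": fyn_lib2_layout,
    "zap70_lib2": zap70_lib2_layout,
}


def builtin_layout(name: str) -> LibraryLayout:
    try:
        return _BUILTIN_LAYOUTS[name]()
    except KeyError:
        raise ValueError(
            f"unknown layout {name!r}; available: {sorted(_BUILTIN_LAYOUTS)}"
        ) from None


def layout_from_dict(data: Mapping) -> LibraryLayout:
    if "layout" in data and len(data) == 1:
        return builtin_layout(str(data["layout"]))
    return LibraryLayout(
        name=str(data.get("name", "")),
        template_substrate=str(data["template_substrate"]),
        variable_positions=tuple(data["variable_positions"]),
        tyrosine_position=int(data["tyrosine_position"]),
        upstream_flank_dna=str(data["upstream_flank_dna"]),
        downstream_flank_dna=str(data["downstream_flank_dna"]),
        variable_region_length_nt=int(data.get("variable_region_length_nt", 0)),
    )


def layout_from_yaml(path: str | Path) -> LibraryLayout:
    """Load a library layout from a YAML/JSON config file.

    The file either names a built-in layout (``layout: fyn_lib2``) or spells
    out the LibraryLayout fields.
    """
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if isinstance(data, str):
        return builtin_layout(data)
    return layout_from_dict(data)
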