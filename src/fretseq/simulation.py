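"""Generative model of a FACS-sorted biosensor library sequencing experiment.

The simulator produces the full study with known ground truth:

1. a skewed (log-normal) abundance distribution over distinct substrate
   variants, a subset of which are *responsive* (desired biosensors: low
   off-state ECFP/FRET ratio with a kinase-dead domain, large positive
   ratio shift with the active kinase) and a small subset *misfolded*
   (high ratio in both kinase contexts — the classic sort-seq false
   positive);
2. per-cell ECFP/FRET ratios for independent active-kinase (KA) and
   kinase-dead (KD) cell populations, Gaussian around each variant's mean;
3. top/bottom ~5% tail gating against the population median, yielding the
   four sorted pools KAH/KAL/KDH/KDL plus the two unsorted input pools;
4. 50-bp single-end reads over the substrate amplicon with independent
   per-base substitution errors, written as Phred+33 FASTQ.

Everything is deterministic given the config seed; identical configs give
byte-identical FASTQ output.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .library_design import (
    AA20,
    LibraryLayout,
    codons_for_aa,
    fyn_lib2_layout,
)

Context = Literal["KA", "KD"]

POOL_FILES = {
    "INPUT_KA": "INPUT_KA.fastq",
    "KAH": "KAH.fastq",
    "KAL": "KAL.fastq",
    "INPUT_KD": "INPUT_KD.fastq",
    "KDH": "KDH.fastq",
    "KDL": "KDL.fastq",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass
class SimulationConfig:
    """Study conditions for one simulated sorted-library experiment.

    Ratio parameters are dimensionless ECFP/FRET units.  Responsive
    (desired) variants draw a tight, low off-state basal ratio and a
    positive kinase-dependent shift; misfolded variants sit high in both
    contexts; all remaining variants draw a neutral basal ratio and no
    shift.
    """

    n_variants: int = 500
    abundance_dispersion: float = 1.0        # sigma of the log-normal library skew
    fraction_responsive: float = 0.10
    fraction_misfolded: float = 0.02
    basal_ratio_mean: float = 1.0
    basal_ratio_sd: float = 0.15
    responsive_basal_mean: float = 0.80
    responsive_basal_sd: float = 0.05
    misfolded_basal_mean: float = 1.50
    misfolded_basal_sd: float = 0.10
    shift_mean: float = 0.60
    shift_sd: float = 0.10
    cell_noise_sd: float = 0.15
    n_cells_per_context: int = 50_000
    sort_fraction: float = 0.05
    reads_per_pool: int = 200_000
    per_base_error_rate: float = 0.001
    read_length: int = 50
    low_quality_rate: float = 0.0            # per-base chance of a Q<=20 score
    indel_rate: float = 0.0                  # per-read chance of a 1-nt deletion
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sort_fraction < 0.5:
            raise ValueError("sort_fraction must be in (0, 0.5)")
        if not 0 <= self.fraction_responsive <= 1:
            raise ValueError("fraction_responsive must be in [0, 1]")
        if not 0 <= self.per_base_error_rate <= 0.1:
            raise ValueError("per_base_error_rate must be in [0, 0.1]")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class SimulationTruth:
    """Ground truth per variant: identity, abundance and FRET behavior."""

    dna: list[str]
    aa: list[str]
    abundance: np.ndarray
    basal_ratio: np.ndarray
    shift: np.ndarray
    responsive: np.ndarray
    misfolded: np.ndarray

    @property
    def n_variants(self) -> int:
        return len(self.dna)

    def mean_ratio(self, context: Context) -> np.ndarray:
        """Per-variant mean ECFP/FRET ratio in the given kinase context."""
        if context == "KA":
            return self.basal_ratio + self.shift
        if context == "KD":
            return self.basal_ratio.copy()
        raise ValueError(f"context must be 'KA' or 'KD', got {context!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": np.arange(self.n_variants),
                "dna": self.dna,
                "aa": self.aa,
                "abundance": self.abundance,
                "basal_ratio": self.basal_ratio,
                "shift": self.shift,
                "responsive": self.responsive,
                "misfolded": self.misfolded,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimulationTruth":
        df = pd.read_csv(path, sep="\t")
        return cls(
            dna=df["dna"].tolist(),
            aa=df["aa"].tolist(),
            abundance=df["abundance"].to_numpy(float),
            basal_ratio=df["basal_ratio"].to_numpy(float),
            shift=df["shift"].to_numpy(float),
            responsive=df["responsive"].to_numpy(bool),
            misfolded=df["misfolded"].to_numpy(bool),
        )


@dataclass(frozen=True)
class CellRecord:
    variant_id: int
    context: Context
    fret_ratio: float


@dataclass
class CellPopulation:
    """A set of cells as parallel arrays (variant index, ECFP/FRET ratio)."""

    context: Context
    variant_idx: np.ndarray
    fret_ratio: np.ndarray

    def __len__(self) -> int:
        return len(self.variant_idx)

    def records(self) -> Iterator[CellRecord]:
        for v, r in zip(self.variant_idx, self.fret_ratio):
            yield CellRecord(int(v), self.context, float(r))

    def subset(self, index: np.ndarray) -> "CellPopulation":
        return CellPopulation(
            context=self.context,
            variant_idx=self.variant_idx[index],
            fret_ratio=self.fret_ratio[index],
        )


def _all_aa_triples() -> list[str]:
    import itertools

    return ["".join(t) for t in itertools.product(AA20, repeat=3)]


_AA_TRIPLES = _all_aa_triples()


def draw_truth(config: SimulationConfig, rng: np.random.Generator | None = None) -> SimulationTruth:
    """Draw the ground-truth library for a config (deterministic given seed).

    Variants are distinct stop-free tripeptides sampled uniformly from the
    20^3 space, each spelled by one randomly chosen synonymous NNK codon
    triple.  Abundances are log-normal with the configured dispersion,
    normalized to sum to one.  Exactly ceil(fraction_responsive * n)
    variants are responsive and ceil(fraction_misfolded * n) of the
    remainder are misfolded-high-basal.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_variants
    if n > len(_AA_TRIPLES):
        raise ValueError("n_variants exceeds the 8000 distinct tripeptides")
    aa_idx = rng.choice(len(_AA_TRIPLES), size=n, replace=False)
    aa = [_AA_TRIPLES[i] for i in aa_idx]
    dna = [
        "".join(rng.choice(codons_for_aa(res)) for res in triple) for triple in aa
    ]

    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_dispersion, size=n)
    abundance /= abundance.sum()

    n_resp = math.ceil(config.fraction_responsive * n)
    n_misf = min(math.ceil(config.fraction_misfolded * n), n - n_resp)
    order = rng.permutation(n)
    resp_idx = order[:n_resp]
    misf_idx = order[n_resp:n_resp + n_misf]

    responsive = np.zeros(n, dtype=bool)
    responsive[resp_idx] = True
    misfolded = np.zeros(n, dtype=bool)
    misfolded[misf_idx] = True

    basal = rng.normal(config.basal_ratio_mean, config.basal_ratio_sd, size=n)
    basal[resp_idx] = rng.normal(
        config.responsive_basal_mean, config.responsive_basal_sd, size=n_resp
    )
    basal[misf_idx] = rng.normal(
        config.misfolded_basal_mean, config.misfolded_basal_sd, size=n_misf
    )
    basal = np.clip(basal, 0.05, None)

    shift = np.zeros(n)
    shift[resp_idx] = np.clip(
        rng.normal(config.shift_mean, config.shift_sd, size=n_resp), 0.0, None
    )

    return SimulationTruth(
        dna=dna,
        aa=aa,
        abundance=abundance,
        basal_ratio=basal,
        shift=shift,
        responsive=responsive,
        misfolded=misfolded,
    )


def simulate_cells(
    truth: SimulationTruth,
    context: Context,
    n_cells: int,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> CellPopulation:
    """Sample a cell population: variant per abundance, Gaussian ratio noise.

    Each cell's ratio is its variant's context mean plus N(0, noise_sd),
    truncated just above zero (a fluorescence ratio cannot be negative).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(truth.n_variants, size=n_cells, p=truth.abundance)
    means = truth.mean_ratio(context)[idx]
    ratios = means + rng.normal(0.0, noise_sd, size=n_cells)
    ratios = np.clip(ratios, 1e-6, None)
    return CellPopulation(context=context, variant_idx=idx, fret_ratio=ratios)


def gate_pools(
    cells: CellPopulation, sort_fraction: float
) -> tuple[CellPopulation, CellPopulation]:
    """Top/bottom tail gates: the floor(fraction*n) highest- and lowest-ratio cells.

    Mirrors sorting the ~5% of cells above/below the population median into
    the high- and low-FRET-ratio pools.  Ties are broken by stable sort on
    (ratio, cell index) so output is platform-independent.
    """
    n = len(cells)
    k = int(np.floor(n * sort_fraction))
    if k < 1:
        raise ValueError("too few cells for the requested sort fraction")
    order = np.argsort(cells.fret_ratio, kind="stable")
    low = cells.subset(order[:k])
    high = cells.subset(order[n - k:])
    return high, low


def _phred_for_error_rate(p: float) -> int:
    if p <= 0:
        return 40
    return int(np.clip(round(-10.0 * math.log10(p)), 2, 40))


def write_reads(
    pool: CellPopulation,
    truth: SimulationTruth,
    layout: LibraryLayout,
    reads_per_pool: int,
    per_base_error_rate: float,
    read_length: int,
    seed: int | np.random.Generator,
    path: str | Path,
    pool_name: str = "pool",
    low_quality_rate: float = 0.0,
    indel_rate: float = 0.0,
) -> int:
    """Sequence a sorted pool: sample cells uniformly, emit error-bearing FASTQ.

    Each read is the amplicon of the sampled cell's variant with independent
    per-base substitutions (uniform over the three alternative bases).  All
    bases carry the Phred score implied by the error rate; an optional
    ``low_quality_rate`` sprinkles Q11 positions to exercise downstream QC,
    and ``indel_rate`` deletes one base from a read to exercise the length
    filter.  Returns the number of records written.
    """
    if layout.read_length > read_length:
        raise ValueError(
            f"amplicon ({layout.read_length} nt) does not fit read_length {read_length}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_reads = int(reads_per_pool)

    amplicons = np.frombuffer(
        "".join(layout.read_for_variant(d) for d in truth.dna).encode(), dtype=np.uint8
    ).reshape(truth.n_variants, layout.read_length)

    cell_choice = rng.integers(0, len(pool), size=n_reads)
    variant_of_read = pool.variant_idx[cell_choice]
    seqs = amplicons[variant_of_read].copy()

    if per_base_error_rate > 0:
        err = rng.random(seqs.shape) < per_base_error_rate
        if err.any():
            base_idx = _BASE_INDEX[seqs[err]].astype(np.int64)
            offset = rng.integers(1, 4, size=base_idx.shape)
            seqs[err] = _BASES[(base_idx + offset) % 4]

    q_good = _phred_for_error_rate(per_base_error_rate)
    quals = np.full(seqs.shape, q_good + 33, dtype=np.uint8)
    if low_quality_rate > 0:
        lowq = rng.random(seqs.shape) < low_quality_rate
        quals[lowq] = 11 + 33

    drop = (
        np.nonzero(rng.random(n_reads) < indel_rate)[0] if indel_rate > 0 else np.array([], int)
    )
    drop_pos = rng.integers(0, layout.read_length, size=len(drop))
    drop_map = dict(zip(drop.tolist(), drop_pos.tolist()))

    with open(path, "wb") as out:
        chunks: list[bytes] = []
        for i in range(n_reads):
            seq = seqs[i].tobytes()
            qual = quals[i].tobytes()
            if i in drop_map:
                p = drop_map[i]
                seq = seq[:p] + seq[p + 1:]
                qual = qual[:p] + qual[p + 1:]
            chunks.append(
                b"@%s:%d\n%s\n+\n%s\n" % (pool_name.encode(), i, seq, qual)
            )
            if len(chunks) >= 50_000:
                out.write(b"".join(chunks))
                chunks.clear()
        out.write(b"".join(chunks))
    return n_reads


def simulate_experiment(
    config: SimulationConfig,
    layout: LibraryLayout | None = None,
    outdir: str | Path = ".",
) -> tuple[SimulationTruth, dict[str, Path]]:
    """Run the full generative experiment and write its outputs.

    Simulates independent KA- and KD-context cell populations from shared
    truth, gates the ~sort_fraction tails of each, and sequences six pools
    (per-context input, high, low) to FASTQ.  Also writes the truth table
    (TSV) and the echoed config (JSON).  Returns the truth and a map of
    pool name -> FASTQ path.
    """
    if layout is None:
        layout = fyn_lib2_layout()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(config.seed)
    ss_truth, ss_ka, ss_kd, ss_reads = root.spawn(4)
    truth = draw_truth(config, rng=np.random.default_rng(ss_truth))

    read_streams = {
        name: np.random.default_rng(ss)
        for name, ss in zip(POOL_FILES, ss_reads.spawn(len(POOL_FILES)))
    }

    paths: dict[str, Path] = {}
    for context, ss_ctx in (("KA", ss_ka), ("KD", ss_kd)):
        pop = simulate_cells(
            truth,
            context,
            config.n_cells_per_context,
            config.cell_noise_sd,
            np.random.default_rng(ss_ctx),
        )
        high, low = gate_pools(pop, config.sort_fraction)
        pools = {
            f"INPUT_{context}": pop,
            f"K{context[1]}H": high,
            f"K{context[1]}L": low,
        }
        for name, pool in pools.items():
            path = outdir / POOL_FILES[name]
            write_reads(
                pool,
                truth,
                layout,
                config.reads_per_pool,
                config.per_base_error_rate,
                config.read_length,
                read_streams[name],
                path,
                pool_name=name,
                low_quality_rate=config.low_quality_rate,
                indel_rate=config.indel_rate,
            )
            paths[name] = path

    truth.to_tsv(outdir / "truth.tsv")
    config.to_json(outdir / "config.json")
    return truth, paths
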