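"""Synthetic datasets with the statistical structure the analyses assume.

Three generators make every downstream stage testable without the study's
raw data:

* :func:`simulate_zinb_counts` — per-pupa bacterial loads as a zero-inflated
  negative binomial, the forward direction of the model the resampling
  engine fits;
* :func:`simulate_ct_dataset` — qPCR CT tables with planted log2 expression
  effects, replicate noise, and an untouched housekeeping gene;
* :func:`plant_motif_sequence` — an i.i.d. background promoter with motif
  consensus sites written at known positions.

Simulated bacterial counts are generated directly on the per-pupa scale
(the scale the regression models), so the plate-dilution scaling is an
identity here; real plating data enters through the 6x factor in
:mod:`pupamp.cfu`.

All generators take an integer seed and derive one counter-based RNG stream
per dataset from (seed, dataset label), so results do not depend on the
order in which stages or cells are generated.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from pupamp.io import NUCLEOTIDES, PfmRecord, validate_cfu_table, validate_ct_table


def _stream(seed: int, label: str) -> np.random.Generator:
    key = zlib.crc32(label.encode())
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    return np.random.Generator(np.random.PCG64(ss))


@dataclasses.dataclass(frozen=True)
class StageParams:
    """ZINB parameters for one stage: structural-zero probability ``pi``,
    NB2 mean ``mu`` and dispersion ``theta`` (variance mu + mu^2/theta)."""

    pi: float
    mu: float
    theta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must lie in [0, 1], got {self.pi}")
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")


@dataclasses.dataclass(frozen=True)
class ZinbSimSpec:
    """Per-stage ZINB parameters for one genotype x bacterium dataset.

    The default is the control-like condition: most individuals clear their
    bacteria (structural-zero fractions 0.83 at P0 and 0.93 at pharate), and
    carriers' mean load drops an order of magnitude across metamorphosis
    (800 -> 80), i.e. a count-component stage coefficient of log(80/800)
    ~ -2.3.  100 individuals per stage, matching the study's plating design.
    """

    p0: StageParams = StageParams(pi=0.83, mu=800.0, theta=0.3)
    pharate: StageParams = StageParams(pi=0.93, mu=80.0, theta=0.3)
    n_per_stage: int = 100
    genotype: str = "control"
    bacterium: str = "Lactobacillus"

    def __post_init__(self) -> None:
        if self.n_per_stage < 1:
            raise ValueError(f"n_per_stage must be >= 1, got {self.n_per_stage}")


def control_like_spec(bacterium: str = "Lactobacillus") -> ZinbSimSpec:
    """Loads falling across metamorphosis (clearance succeeds)."""
    return ZinbSimSpec(genotype="control", bacterium=bacterium)


def ecrdn_like_spec(bacterium: str = "Lactobacillus") -> ZinbSimSpec:
    """Loads rising across metamorphosis, as when ecdysone signalling (and
    hence the systemic AMP response) is disabled: the stage parameters of
    the control condition are mirrored so the carrier mean climbs 80 -> 800."""
    return ZinbSimSpec(
        p0=StageParams(pi=0.93, mu=80.0, theta=0.3),
        pharate=StageParams(pi=0.83, mu=800.0, theta=0.3),
        genotype="EcRDN",
        bacterium=bacterium,
    )


def _zinb_draw(
    rng: np.random.Generator, params: StageParams, n: int
) -> np.ndarray:
    """n draws: zero with probability pi, else NB2(mu, theta) via the
    gamma-Poisson mixture."""
    structural = rng.random(n) < params.pi
    lam = rng.gamma(shape=params.theta, scale=params.mu / params.theta, size=n)
    counts = rng.poisson(lam)
    counts[structural] = 0
    return counts


def simulate_zinb_counts(spec: ZinbSimSpec, seed: int) -> pd.DataFrame:
    """A CFU dataset drawn from the ZINB forward model.

    Returns a validated CFU table with ``n_per_stage`` rows per stage;
    counts appear identically as ``colonies`` and ``cfu_per_pupa`` (see
    module docstring).
    """
    label = f"zinb:{spec.genotype}:{spec.bacterium}"
    rng = _stream(seed, label)
    frames = []
    for stage, params in (("P0", spec.p0), ("pharate", spec.pharate)):
        counts = _zinb_draw(rng, params, spec.n_per_stage)
        frames.append(
            pd.DataFrame(
                {
                    "genotype": spec.genotype,
                    "stage": stage,
                    "bacterium": spec.bacterium,
                    "colonies": counts,
                    "cfu_per_pupa": counts.astype(float),
                }
            )
        )
    return validate_cfu_table(pd.concat(frames, ignore_index=True), source=label)


@dataclasses.dataclass(frozen=True)
class CtSimSpec:
    """Design for a synthetic qPCR CT table.

    ``effects`` plants per-cell log2 expression differences relative to the
    calibrator: CT(target) = baseline - effect + Gaussian noise, so a +3
    effect yields a fold-change of 8 downstream.  The housekeeping gene is
    untouched by effects.  Each biological sample stands for a pool of five
    individuals, as in the study's qPCR design.
    """

    genotypes: tuple[str, ...] = ("control",)
    stages: tuple[str, ...] = ("L3", "P0")
    genes: tuple[str, ...] = ("drs",)
    baseline_ct: dict | None = None  # gene -> CT at calibrator expression
    reference_gene: str = "rpl32"
    reference_ct: float = 18.0
    effects: dict | None = None  # (genotype, stage, gene) -> log2 effect
    noise_sd: float = 0.2
    replicates: int = 2
    samples_per_cell: int = 5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.samples_per_cell < 1:
            raise ValueError("samples_per_cell must be >= 1")
        object.__setattr__(
            self,
            "baseline_ct",
            dict(self.baseline_ct or {g: 28.0 for g in self.genes}),
        )
        object.__setattr__(self, "effects", dict(self.effects or {}))


def simulate_ct_dataset(spec: CtSimSpec, seed: int) -> pd.DataFrame:
    """A fully crossed CT replicate table with planted expression effects."""
    rng = _stream(seed, "ct:" + ",".join(spec.genotypes) + ":" + ",".join(spec.genes))
    rows = []
    for genotype in spec.genotypes:
        for stage in spec.stages:
            for s in range(spec.samples_per_cell):
                sample_id = f"{genotype}_{stage}_{s + 1}"
                for gene in (*spec.genes, spec.reference_gene):
                    if gene == spec.reference_gene:
                        base = spec.reference_ct
                        effect = 0.0
                    else:
                        base = spec.baseline_ct[gene]
                        effect = spec.effects.get((genotype, stage, gene), 0.0)
                    for rep in range(spec.replicates):
                        noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0
                        ct = max(base - effect + noise, 1e-6)
                        rows.append(
                            {
                                "sample_id": sample_id,
                                "genotype": genotype,
                                "stage": stage,
                                "gene": gene,
                                "ct": ct,
                                "replicate": rep + 1,
                            }
                        )
    return validate_ct_table(
        pd.DataFrame(rows), reference_gene=spec.reference_gene, source="ct simulation"
    )


def plant_motif_sequence(
    length: int,
    background: np.ndarray,
    pfm: PfmRecord,
    site_positions: list[int],
    seed: int,
) -> tuple[SeqRecord, list[int]]:
    """An i.i.d. background sequence with the PFM consensus planted at the
    given (non-overlapping, 0-based) positions.

    Returns the sequence record and the ground-truth site list.
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg < 0).any() or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 probabilities summing to 1")
    L = pfm.length
    positions = sorted(int(p) for p in site_positions)
    for p in positions:
        if p < 0 or p + L > length:
            raise ValueError(f"site at {p} does not fit in a length-{length} sequence")
    for a, b in zip(positions, positions[1:]):
        if b < a + L:
            raise ValueError(f"sites at {a} and {b} overlap")

    rng = _stream(seed, f"promoter:{length}:{','.join(map(str, positions))}")
    bases = np.array(list(NUCLEOTIDES))
    seq = rng.choice(bases, size=length, p=bg)
    consensus = pfm.consensus()
    for p in positions:
        seq[p : p + L] = list(consensus)
    record = SeqRecord(
        Seq("".join(seq)),
        id="synthetic_promoter",
        description=f"iid background with {len(positions)} planted consensus sites",
    )
    return record, positions
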