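"""Configuration objects for the synthetic amphidiploid / BAC-library simulator.

The defaults describe the study conditions the simulator emulates: two
progenitor genome regions of ~1 Mbp diverged to ~96% identity, an
amphidiploid carrying both homoeologs with accession-level SNPs at
0.82–1.98% per site, a 10x clone library of 82,944 coordinates on 216
384-well plates with 135–150 kbp inserts, a panel of 52 intergenomic SNP
assays with the five-category pathology mix, and GoldenGate-style noisy
pool signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple


@dataclass
class NoiseModel:
    """Noise applied to per-pool genotyping signals.

    pool_dropout_prob
        Probability that a truly positive (pool, assay) signal falls below
        the intensity threshold (the pool "did not yield a signal above the
        applied threshold").
    nucleotide_flip_prob
        Probability that a positive pool is ascribed to the wrong assay
        nucleotide (its allele-frequency angle is mirrored).
    residual_r
        (mean, sd) of the residual normalised intensity of negative pools.
    positive_r
        (mean, sd) of the normalised intensity of positive pools.
    theta_jitter_sd
        Gaussian jitter of the normalised Theta around its ideal value.
    """

    pool_dropout_prob: float = 0.02
    nucleotide_flip_prob: float = 0.005
    residual_r: Tuple[float, float] = (0.05, 0.03)
    positive_r: Tuple[float, float] = (0.6, 0.15)
    theta_jitter_sd: float = 0.01

    def validate(self) -> None:
        for name in ("pool_dropout_prob", "nucleotide_flip_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("residual_r", "positive_r"):
            mean, sd = getattr(self, name)
            if mean < 0 or sd < 0:
                raise ValueError(f"{name} parameters must be non-negative")
        if self.theta_jitter_sd < 0:
            raise ValueError("theta_jitter_sd must be non-negative")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        """All stochastic signal pathologies switched off."""
        return cls(
            pool_dropout_prob=0.0,
            nucleotide_flip_prob=0.0,
            residual_r=(0.05, 0.0),
            positive_r=(0.6, 0.0),
            theta_jitter_sd=0.0,
        )


@dataclass
class SimulationConfig:
    """Parameters of one synthetic amphidiploid screening experiment.

    The library size is ``n_plates * rows_per_plate * cols_per_plate``
    (default 216 x 16 x 24 = 82,944 coordinates).  ``genome_length_bp`` is
    rescaled at library-simulation time so that library size x mean insert
    / total genome length equals ``coverage_target``.
    """

    region_length_bp: int = 1_000_000
    genome_length_bp: int = 1_200_000_000
    divergence_rate: float = 0.037
    indel_rate: float = 0.0005
    indel_mean_len: float = 3.0
    accession_snp_rate_range: Tuple[float, float] = (0.0082, 0.0198)
    n_plates: int = 216
    rows_per_plate: int = 16
    cols_per_plate: int = 24
    insert_size_mean_bp: int = 142_500
    insert_size_sd_bp: int = 15_000
    insert_size_min_bp: int = 20_000
    coverage_target: float = 10.0
    n_assays: int = 52
    # category 1..5 fractions; approximates the realised panel of the
    # reference screen (23/13/6 assays in categories 1-3 of 52, eight
    # single-nucleotide assays, a few amphidiploid-monomorphic sites).
    assay_category_mix: Tuple[float, float, float, float, float] = (
        0.44, 0.25, 0.12, 0.13, 0.06)
    off_target_fraction: float = 0.05
    diagonal_modulus: int = 23
    n_masked_amplicons: int = 1
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    @property
    def library_size(self) -> int:
        return self.n_plates * self.rows_per_plate * self.cols_per_plate

    @property
    def wells_per_plate(self) -> int:
        return self.rows_per_plate * self.cols_per_plate

    def validate(self) -> None:
        if self.region_length_bp < 10_000:
            raise ValueError(
                "region_length_bp must be at least 10,000 bp "
                f"(got {self.region_length_bp})")
        if not (0.0 <= self.divergence_rate < 1.0):
            raise ValueError("divergence_rate must be in [0, 1)")
        if self.indel_rate < 0 or self.indel_mean_len < 1:
            raise ValueError("invalid indel model parameters")
        lo, hi = self.accession_snp_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("accession_snp_rate_range must be an ordered "
                             "pair of fractions")
        if min(self.n_plates, self.rows_per_plate, self.cols_per_plate) < 0:
            raise ValueError("library dimensions must be non-negative")
        if self.insert_size_mean_bp <= 0 or self.insert_size_sd_bp < 0:
            raise ValueError("invalid insert size model")
        if abs(sum(self.assay_category_mix) - 1.0) > 1e-6:
            raise ValueError("assay_category_mix must sum to 1")
        if self.diagonal_modulus < 1:
            raise ValueError("diagonal_modulus must be >= 1")
        self.noise.validate()

    def as_dict(self) -> dict:
        return asdict(self)
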