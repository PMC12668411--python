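"""Parameter blocks for every pipeline stage.

Each stage of the pipeline takes one of the models below. They double as the
stage blocks of the YAML pipeline configuration: unknown keys are rejected,
defaults are injected, and range constraints are enforced at construction
time, so a config error surfaces before any stage runs.

Defaults follow the published protocol wherever it states a value
(UMI floor 500, 3 MADs, 8% mito cap, 40 doublet iterations, 50% vote,
1e-7 cluster p, normalization target 10,000, 3,000 HVGs, 30-dim embedding,
k=15 neighbors, 10 diffusion components, MI n_neighbors=3, 1,000
permutations, q<0.05, 90th percentile, 1% expression floor, 20 splines,
800 grid points, 1st/99th percentile normalization, spatial k=5 with
98th/95th percentile outlier rule, RBF length scale 1.0 + white noise 1e-3,
200x200 grid, blur sigma 10).
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


# ---------------------------------------------------------------- simulation


class ReadErrorRates(_Block):
    """Per-read corruption probabilities for simulated spatial-barcode reads."""

    p_umi_N: float = Field(0.02, ge=0.0, le=1.0)
    p_up_mismatch: float = Field(0.05, ge=0.0, le=1.0)
    p_up_deletion: float = Field(0.02, ge=0.0, le=1.0)
    p_bc_mismatch: float = Field(0.05, ge=0.0, le=1.0)
    p_chimera: float = Field(0.02, ge=0.0, le=1.0)


class SimConfig(_Block):
    """Synthetic-data generator settings.

    The generator emulates a circular barcoded bead array read out by a
    droplet library: cells sit in a disc of radius ``array_radius``, their
    latent differentiation time increases linearly from the periphery to
    the center (t = 1 - r/R), and each cell sheds spatial-barcode reads
    from beads near its true position (Gaussian kernel of scale
    ``diffusion_sigma``).
    """

    n_beads: int = Field(5000, gt=0)
    array_radius: float = Field(1000.0, gt=0.0)
    bead_barcode_len: int = Field(15, gt=0)
    n_cells: int = Field(300, gt=0)
    n_genes: int = Field(500, gt=0)
    frac_mito_genes: float = Field(0.05, ge=0.0, le=1.0)
    nb_dispersion: float = Field(2.0, gt=0.0)
    umi_depth_mean: float = Field(2000.0, gt=0.0)
    responsive_frac: float = Field(0.1, ge=0.0, le=1.0)
    response_amplitude: float = Field(2.0, gt=0.0)
    shared_ortholog_frac: float = Field(0.5, ge=0.0, le=1.0)
    doublet_rate: float = Field(0.05, ge=0.0, le=1.0)
    read_error_rates: ReadErrorRates = Field(default_factory=ReadErrorRates)
    reads_per_cell_mean: float = Field(60.0, gt=0.0)
    diffusion_sigma: float = Field(25.0, gt=0.0)
    seed: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _barcode_space(self) -> "SimConfig":
        if self.n_beads > 4 ** self.bead_barcode_len:
            raise ValueError(
                f"n_beads={self.n_beads} exceeds the barcode space "
                f"4^{self.bead_barcode_len}"
            )
        return self


# ----------------------------------------------------------- read placement


class DbscanParams(_Block):
    """DBSCAN settings for classifying a cell's beads into signal vs noise.

    ``eps_grid``/``min_pts_grid`` are candidate hyperparameter grids; the
    pair maximizing the placement score (fraction of cells with exactly one
    signal cluster holding >=50% of the cell's UMIs) is chosen, ties broken
    toward smaller eps. When ``eps_grid`` is None it is derived from the
    median nearest-bead spacing of the whitelist (multiples 1.5/2.5/4/6).
    """

    eps_grid: Optional[tuple[float, ...]] = None
    min_pts_grid: tuple[int, ...] = (3, 5, 10)
    min_cluster_umi_frac: float = Field(0.5, gt=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "DbscanParams":
        if self.eps_grid is not None and any(e <= 0 for e in self.eps_grid):
            raise ValueError("eps values must be positive")
        if any(m < 2 for m in self.min_pts_grid):
            raise ValueError("min_pts must be >= 2")
        return self


class ChimeraParams(_Block):
    """Within a (cell, UMI) group spanning several beads, keep the dominant
    bead if it holds at least ``top_frac`` of the group's reads, else drop
    the group."""

    top_frac: float = Field(0.8, gt=0.5, le=1.0)


# -------------------------------------------------------------------- QC


class QcThresholds(_Block):
    min_umi: int = Field(500, ge=0)
    mad_k: float = Field(3.0, gt=0.0)
    mito_max: float = Field(0.08, gt=0.0, le=1.0)


class DoubletParams(_Block):
    n_iterations: int = Field(40, gt=0)
    voter_threshold: float = Field(0.5, gt=0.0, le=1.0)
    cluster_p_threshold: float = Field(1e-7, gt=0.0, lt=1.0)
    n_synthetic: Optional[int] = Field(None, gt=0)  # default: one per real cell
    n_hvgs: int = Field(3000, gt=0)
    n_pcs: int = Field(30, gt=1)
    n_neighbors: int = Field(15, gt=1)
    resolution: float = Field(1.0, gt=0.0)
    seed: int = Field(0, ge=0)


# ------------------------------------------------------------- trajectory


class TrajectoryParams(_Block):
    target_sum: float = Field(10_000.0, gt=0.0)
    n_hvgs: int = Field(3000, gt=0)
    n_components: int = Field(30, ge=2)
    k_neighbors: int = Field(15, gt=1)
    n_diffusion_comps: int = Field(10, gt=1)


# -------------------------------------------------- pseudotime-gene testing


class PermutationConfig(_Block):
    n_permutations: int = Field(1000, ge=1)
    mi_neighbors: int = Field(3, ge=1)
    q_threshold: float = Field(0.05, gt=0.0, lt=1.0)
    top_percentile: float = Field(90.0, gt=0.0, lt=100.0)
    min_expr_frac: float = Field(0.01, ge=0.0, le=1.0)
    seed: int = Field(0, ge=0)


# ----------------------------------------------------------- trend heatmap


class GamConfig(_Block):
    n_splines: int = Field(20, ge=4)
    grid_points: int = Field(800, ge=2)
    norm_low_pct: float = Field(1.0, ge=0.0, lt=100.0)
    norm_high_pct: float = Field(99.0, gt=0.0, le=100.0)
    division_guard: float = Field(1e-8, gt=0.0)


# ------------------------------------------------------------ spatial field


class OutlierParams(_Block):
    k_spatial: int = Field(5, ge=1)
    dist_percentile: float = Field(98.0, gt=0.0, lt=100.0)
    dt_percentile: float = Field(95.0, gt=0.0, lt=100.0)


class FieldParams(_Block):
    grid_shape: tuple[int, int] = (200, 200)
    rbf_length_scale: float = Field(1.0, gt=0.0)
    white_noise: float = Field(1e-3, gt=0.0)
    blur_sigma: float = Field(10.0, ge=0.0)
    grid_margin: float = Field(0.02, ge=0.0)
    blur_before_gradient: bool = True

    @model_validator(mode="after")
    def _check(self) -> "FieldParams":
        if any(g < 2 for g in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 2")
        return self


# ----------------------------------------------------------------- pipeline


class StageFlags(_Block):
    simulate: bool = True
    position: bool = True
    qc: bool = True
    trajectory: bool = True
    mi_genes: bool = True
    cross_species: bool = True
    trends: bool = True
    field: bool = True


class PipelineConfig(_Block):
    """Top-level pipeline configuration: one block per stage plus IO."""

    seed: int = Field(0, ge=0)
    out_dir: str = "spatime_out"
    stages: StageFlags = Field(default_factory=StageFlags)
    sim: SimConfig = Field(default_factory=SimConfig)
    dbscan: DbscanParams = Field(default_factory=DbscanParams)
    chimera: ChimeraParams = Field(default_factory=ChimeraParams)
    qc: QcThresholds = Field(default_factory=QcThresholds)
    doublets: DoubletParams = Field(default_factory=DoubletParams)
    trajectory: TrajectoryParams = Field(default_factory=TrajectoryParams)
    permutation: PermutationConfig = Field(default_factory=PermutationConfig)
    gam: GamConfig = Field(default_factory=GamConfig)
    outliers: OutlierParams = Field(default_factory=OutlierParams)
    field: FieldParams = Field(default_factory=FieldParams)
    # optional external inputs used when the simulate stage is disabled
    input_fastq_r1: Optional[str] = None
    input_fastq_r2: Optional[str] = None
    input_whitelist: Optional[str] = None
    input_counts_dir: Optional[str] = None

    @model_validator(mode="after")
    def _inputs_present(self) -> "PipelineConfig":
        if not self.stages.simulate and self.stages.position:
            missing = [
                name
                for name, val in [
                    ("input_fastq_r1", self.input_fastq_r1),
                    ("input_fastq_r2", self.input_fastq_r2),
                    ("input_whitelist", self.input_whitelist),
                ]
                if val is None
            ]
            if missing:
                raise ValueError(
                    "simulate stage disabled but no input paths given: "
                    + ", ".join(missing)
                )
        return self


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name.

    Stable across runs and platforms (crc32-based), and below 2**31 so it
    is accepted by every RNG consumer.
    """
    import zlib

    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)
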