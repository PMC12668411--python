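"""Synthetic data generation for every pipeline input.

The generator emulates a spatially barcoded bead array read out through a
droplet snRNA-seq library, for two species at once:

* a circular bead array whose beads carry unique 15-nt spatial barcodes
  (8 + 7 nt flanking an 18-nt universal-primer linker, mirroring the bead
  oligo design);
* cells placed uniformly in the array disc, with a latent differentiation
  pseudotime that increases linearly from the tissue periphery toward the
  center, t = 1 - r/R;
* negative-binomial count matrices in which a configurable fraction of
  genes respond to pseudotime through a Gaussian bump on the log-mean,
  mu_g(t) = b_g * exp(a_g * exp(-(t - c_g)^2 / (2 w_g^2)));
* spatial-barcode read pairs with realistic error processes (N bases in the
  UMI, universal-primer mismatches and deletions, barcode substitutions,
  chimeric bead reassignment), each emitted alongside a per-read truth log;
* droplet doublets as sums of two real cells' count vectors;
* a two-species homology table in the three-column MGI HOM report layout,
  containing both strict one-to-one classes and violating classes.

All randomness flows from ``SimConfig.seed`` through named substreams, so a
fixed config reproduces byte-identical outputs.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import SimConfig

UP_SEQ = "TCTTCAGCGTTCCCGAGA"  # 18-nt universal-primer linker on the bead
BC1_LEN = 8
BC2_LEN = 7
CELL_BC_LEN = 16
UMI_LEN = 12
BEAD_UMI_LEN = 9
ALPHABET = np.array(list("ACGT"))

MOUSE = "mouse, laboratory"
HUMAN = "human"


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, decorrelated RNG substream below 2**31."""
    import zlib

    return np.random.default_rng((seed, zlib.crc32(name.encode())))


def _random_barcodes(rng: np.random.Generator, n: int, length: int,
                     max_attempts: int = 50) -> list[str]:
    """n unique random barcodes over {A,C,G,T}; raises if uniqueness cannot
    be achieved in bounded oversampling attempts."""
    seen: dict[str, None] = {}
    for _ in range(max_attempts):
        draw = rng.integers(0, 4, size=(2 * (n - len(seen)) + 8, length))
        for row in draw:
            bc = "".join(ALPHABET[row])
            if bc not in seen:
                seen[bc] = None
                if len(seen) == n:
                    return list(seen)
    raise RuntimeError(
        f"could not generate {n} unique {length}-nt barcodes "
        f"in {max_attempts} attempts"
    )


# --------------------------------------------------------------------- truth


@dataclass
class SpeciesTruth:
    """Ground truth for one species' simulated cells and genes."""

    species: str
    barcodes: list[str]                 # n_real + n_doublets droplet barcodes
    positions: np.ndarray               # (n_real, 2) true cell coordinates
    pseudotime: np.ndarray              # (n_real,) t = 1 - r/R
    doublet_labels: np.ndarray          # (n_total,) bool
    doublet_pairs: np.ndarray           # (n_doublets, 2) indices into real cells
    genes: pd.DataFrame                 # gene, mito, responsive, center, width, amplitude

    @property
    def n_real(self) -> int:
        return len(self.pseudotime)

    @property
    def responsive_genes(self) -> list[str]:
        return self.genes.loc[self.genes["responsive"], "gene"].tolist()


@dataclass
class SimTruth:
    """Full ground truth: two species plus their ortholog structure."""

    species_a: SpeciesTruth
    species_b: SpeciesTruth
    ortholog_pairs: list[tuple[str, str]]           # (mouse gene, human gene)
    shared_responsive_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Truth tables as plain DataFrames (for TSV export)."""
        out = {}
        for sp in (self.species_a, self.species_b):
            n_real = sp.n_real
            cells = pd.DataFrame(
                {
                    "barcode": sp.barcodes,
                    "is_doublet": sp.doublet_labels,
                    "x": np.concatenate(
                        [sp.positions[:, 0], np.full(len(sp.barcodes) - n_real, np.nan)]
                    ),
                    "y": np.concatenate(
                        [sp.positions[:, 1], np.full(len(sp.barcodes) - n_real, np.nan)]
                    ),
                    "pseudotime": np.concatenate(
                        [sp.pseudotime, np.full(len(sp.barcodes) - n_real, np.nan)]
                    ),
                }
            )
            out[f"cells_{sp.species}"] = cells
            out[f"genes_{sp.species}"] = sp.genes.copy()
        out["ortholog_pairs"] = pd.DataFrame(
            self.ortholog_pairs, columns=["mouse_gene", "human_gene"]
        )
        return out


def _make_gene_table(
    rng: np.random.Generator, species: str, n_genes: int, frac_mito: float
) -> pd.DataFrame:
    n_mito = int(round(frac_mito * n_genes))
    if species == MOUSE:
        names = [f"Gene{i:05d}" for i in range(n_genes - n_mito)]
        mito = [f"mt-Gene{i:02d}" for i in range(n_mito)]
    else:
        names = [f"GENE{i:05d}" for i in range(n_genes - n_mito)]
        mito = [f"MT-GENE{i:02d}" for i in range(n_mito)]
    df = pd.DataFrame({"gene": names + mito})
    df["mito"] = df["gene"].str.upper().str.startswith("MT-")
    df["responsive"] = False
    df["center"] = np.nan
    df["width"] = np.nan
    df["amplitude"] = np.nan
    df["baseline"] = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    return df


def _place_cells(rng: np.random.Generator, n: int, radius: float):
    """Uniform positions in the disc; pseudotime rises periphery -> center."""
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    t = 1.0 - r / radius
    return xy, t


def generate_truth(config: SimConfig) -> SimTruth:
    """Draw the latent state every other generator conditions on.

    Responsive genes are selected among non-mitochondrial genes; a fraction
    ``shared_ortholog_frac`` of them are responsive in *both* species through
    their one-to-one ortholog pair, the rest are species-specific (their
    ortholog partner, if any, is kept non-responsive).
    """
    n_resp = int(round(config.responsive_frac * config.n_genes))
    if config.shared_ortholog_frac > 0 and n_resp < 1:
        raise ValueError(
            "shared_ortholog_frac > 0 requires at least one responsive gene "
            "(responsive_frac * n_genes >= 1)"
        )

    species = {}
    for sp, tag in ((MOUSE, "a"), (HUMAN, "b")):
        rng = _substream(config.seed, f"truth_{tag}")
        genes = _make_gene_table(rng, sp, config.n_genes, config.frac_mito_genes)
        xy, t = _place_cells(rng, config.n_cells, config.array_radius)
        n_doub = int(round(config.doublet_rate * config.n_cells))
        pairs = np.empty((n_doub, 2), dtype=np.int64)
        for i in range(n_doub):
            pairs[i] = rng.choice(config.n_cells, size=2, replace=False)
        barcodes = _random_barcodes(rng, config.n_cells + n_doub, CELL_BC_LEN)
        labels = np.zeros(config.n_cells + n_doub, dtype=bool)
        labels[config.n_cells:] = True
        species[tag] = SpeciesTruth(
            species=sp,
            barcodes=barcodes,
            positions=xy,
            pseudotime=t,
            doublet_labels=labels,
            doublet_pairs=pairs,
            genes=genes,
        )

    rng = _substream(config.seed, "orthology")
    sp_a, sp_b = species["a"], species["b"]
    non_mito_a = sp_a.genes.index[~sp_a.genes["mito"]].to_numpy()
    non_mito_b = sp_b.genes.index[~sp_b.genes["mito"]].to_numpy()
    n_pairable = min(len(non_mito_a), len(non_mito_b))
    n_paired = int(round(0.9 * n_pairable))  # 90% of genes have 1:1 orthologs
    paired_a = rng.permutation(non_mito_a)[:n_paired]
    paired_b = rng.permutation(non_mito_b)[:n_paired]
    ortholog_pairs = [
        (sp_a.genes.at[ia, "gene"], sp_b.genes.at[ib, "gene"])
        for ia, ib in zip(paired_a, paired_b)
    ]

    n_shared = int(round(config.shared_ortholog_frac * n_resp))
    n_shared = min(n_shared, n_paired)
    shared_slots = rng.choice(n_paired, size=n_shared, replace=False)
    shared_pairs = []

    def _set_responsive(
        sp: SpeciesTruth, idx: int, params: tuple[float, float, float]
    ):
        sp.genes.at[idx, "responsive"] = True
        sp.genes.at[idx, "center"] = params[0]
        sp.genes.at[idx, "width"] = params[1]
        sp.genes.at[idx, "amplitude"] = params[2]

    def _draw_params(rng_r: np.random.Generator) -> tuple[float, float, float]:
        return (
            rng_r.uniform(0.15, 0.85),
            rng_r.uniform(0.10, 0.25),
            # long-tailed effect sizes: a conserved top program stands out
            config.response_amplitude * rng_r.lognormal(0.0, 0.5),
        )

    # shared pairs inherit one parameter set (and baseline level) in both
    # species: a conserved program keeps its dynamics and expression level
    for s in shared_slots:
        params = _draw_params(rng)
        _set_responsive(sp_a, int(paired_a[s]), params)
        _set_responsive(sp_b, int(paired_b[s]), params)
        sp_b.genes.at[int(paired_b[s]), "baseline"] = sp_a.genes.at[
            int(paired_a[s]), "baseline"
        ]
        shared_pairs.append(ortholog_pairs[s])

    # species-specific responsive genes: partner (if any) stays flat
    for sp, paired, non_mito in (
        (sp_a, paired_a, non_mito_a),
        (sp_b, paired_b, non_mito_b),
    ):
        free = [i for i in non_mito if not sp.genes.at[int(i), "responsive"]]
        taken = {int(paired[s]) for s in shared_slots}
        free = [i for i in free if int(i) not in taken]
        extra = n_resp - n_shared
        for i in rng.permutation(np.array(free, dtype=np.int64))[:extra]:
            _set_responsive(sp, int(i), _draw_params(rng))

    return SimTruth(
        species_a=sp_a,
        species_b=sp_b,
        ortholog_pairs=ortholog_pairs,
        shared_responsive_pairs=shared_pairs,
    )


# --------------------------------------------------------------- bead array


def generate_bead_array(config: SimConfig) -> pd.DataFrame:
    """Bead whitelist: unique spatial barcodes with disc-uniform coordinates.

    Returns a DataFrame with columns ``barcode``, ``x``, ``y``; write with
    :func:`write_whitelist` for the canonical header CSV.
    """
    rng = _substream(config.seed, "beads")
    barcodes = _random_barcodes(rng, config.n_beads, config.bead_barcode_len)
    r = config.array_radius * np.sqrt(rng.random(config.n_beads))
    theta = rng.random(config.n_beads) * 2 * np.pi
    return pd.DataFrame(
        {
            "barcode": barcodes,
            "x": r * np.cos(theta),
            "y": r * np.sin(theta),
        }
    )


def write_whitelist(whitelist: pd.DataFrame, path: str | Path) -> None:
    whitelist.to_csv(path, index=False, float_format="%.6f")


# -------------------------------------------------------------- expression


def bump_mean(t: np.ndarray, center: float, width: float, amplitude: float) -> np.ndarray:
    """Multiplicative pseudotime response: exp(a * exp(-(t-c)^2 / 2w^2))."""
    return np.exp(amplitude * np.exp(-((t - center) ** 2) / (2.0 * width**2)))


def _species_counts(
    config: SimConfig, sp: SpeciesTruth, rng: np.random.Generator
) -> ad.AnnData:
    genes = sp.genes
    n_real = sp.n_real
    n_genes = len(genes)

    baseline = genes["baseline"].to_numpy(np.float64)
    mu = np.tile(baseline, (n_real, 1))
    for idx in genes.index[genes["responsive"]]:
        g = genes.loc[idx]
        mu[:, idx] = baseline[idx] * bump_mean(
            sp.pseudotime, g["center"], g["width"], g["amplitude"]
        )

    # scale to the configured mean depth, with lognormal per-cell size factors
    mu *= config.umi_depth_mean / mu.sum(axis=1).mean()
    size_factor = rng.lognormal(mean=0.0, sigma=0.25, size=n_real)
    mu *= size_factor[:, None]

    theta = config.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(np.int64)

    doublet_rows = counts[sp.doublet_pairs[:, 0]] + counts[sp.doublet_pairs[:, 1]]
    X = np.vstack([counts, doublet_rows])

    adata = ad.AnnData(
        X=X.astype(np.float32),
        obs=pd.DataFrame(
            {"true_doublet": sp.doublet_labels}, index=pd.Index(sp.barcodes, name="cell")
        ),
        var=pd.DataFrame(
            {
                "mt": genes["mito"].to_numpy(),
                "species": sp.species,
                "true_responsive": genes["responsive"].to_numpy(),
            },
            index=pd.Index(genes["gene"], name="gene"),
        ),
    )
    adata.obs["true_pseudotime"] = np.concatenate(
        [sp.pseudotime, np.full(len(sp.barcodes) - n_real, np.nan)]
    )
    return adata


def generate_expression(config: SimConfig, truth: SimTruth) -> tuple[ad.AnnData, ad.AnnData]:
    """Two species-labeled count matrices with negative-binomial noise.

    Rows are droplets (real cells followed by injected doublets), columns
    genes; ``var['mt']`` flags mitochondrial genes and
    ``obs['true_doublet']`` / ``var['true_responsive']`` carry ground truth.
    """
    a = _species_counts(config, truth.species_a, _substream(config.seed, "expr_a"))
    b = _species_counts(config, truth.species_b, _substream(config.seed, "expr_b"))
    return a, b


# ------------------------------------------------------------ spatial reads


@dataclass
class SpatialReadSet:
    """Simulated spatial-barcode read pairs plus the per-read truth log.

    R1 carries cell barcode (16 nt) + library UMI (12 nt); R2 carries
    bc1 (8) + UP linker (18) + bc2 (7) + bead UMI (9).
    """

    r1: list[tuple[str, str]]       # (name, sequence)
    r2: list[tuple[str, str]]
    log: pd.DataFrame

    def write(self, r1_path: str | Path, r2_path: str | Path) -> None:
        for path, records in ((r1_path, self.r1), (r2_path, self.r2)):
            path = str(path)
            opener = gzip.open if path.endswith(".gz") else open
            with opener(path, "wt") as fh:
                for name, seq in records:
                    fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    chars = list(seq)
    pos = rng.choice(len(chars), size=n_sub, replace=False)
    for p in pos:
        alt = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alt[rng.integers(0, 3)]
    return "".join(chars)


def generate_spatial_reads(
    config: SimConfig,
    truth: SimTruth,
    whitelist: pd.DataFrame,
    dup_mean: float = 0.5,
) -> SpatialReadSet:
    """Emit spatial-barcode reads for the primary species' droplets.

    Each droplet sheds Poisson(``reads_per_cell_mean``) molecules; a
    molecule's bead is drawn with probability proportional to a Gaussian
    kernel of the distance between bead and cell (scale ``diffusion_sigma``)
    and is sequenced 1 + Poisson(``dup_mean``) times. Doublet droplets
    alternate molecules between their two constituent cells. Errors are
    injected per read at the configured rates; chimeras keep (cell, UMI)
    but move the read to a uniformly random bead.
    """
    if len(whitelist) == 0:
        raise ValueError("whitelist is empty")
    coords = whitelist[["x", "y"]].to_numpy()
    radii = np.hypot(coords[:, 0], coords[:, 1])
    if (radii > config.array_radius * (1 + 1e-9)).any():
        raise ValueError("whitelist coordinates fall outside array_radius")
    bead_bcs = whitelist["barcode"].to_numpy()
    tree = cKDTree(coords)
    sigma = config.diffusion_sigma
    rng = _substream(config.seed, "reads")
    er = config.read_error_rates

    sp = truth.species_a
    r1: list[tuple[str, str]] = []
    r2: list[tuple[str, str]] = []
    log_rows = []
    read_id = 0

    for ci, cell_bc in enumerate(sp.barcodes):
        if sp.doublet_labels[ci]:
            pair = sp.doublet_pairs[ci - sp.n_real]
            sources = [sp.positions[pair[0]], sp.positions[pair[1]]]
        else:
            sources = [sp.positions[ci]]
        n_mol = rng.poisson(config.reads_per_cell_mean)
        for m in range(n_mol):
            pos = sources[m % len(sources)]
            near = tree.query_ball_point(pos, 4.0 * sigma)
            if not near:
                near = [int(tree.query(pos)[1])]
            near = np.asarray(near)
            d2 = ((coords[near] - pos) ** 2).sum(axis=1)
            w = np.exp(-d2 / (2.0 * sigma**2))
            bead_idx = int(near[rng.choice(len(near), p=w / w.sum())])
            umi = "".join(ALPHABET[rng.integers(0, 4, UMI_LEN)])
            n_reads = 1 + rng.poisson(dup_mean)
            for _ in range(n_reads):
                obs_bead = bead_idx
                chimera = rng.random() < er.p_chimera
                if chimera:
                    obs_bead = int(rng.integers(0, len(bead_bcs)))
                bc = bead_bcs[obs_bead]
                bc_subs = 0
                if rng.random() < er.p_bc_mismatch:
                    bc_subs = int(rng.integers(1, 3))  # 1 or 2
                    bc = _mutate(rng, bc, bc_subs)
                up = UP_SEQ
                up_subs = 0
                if rng.random() < er.p_up_mismatch:
                    up_subs = int(rng.integers(1, 4))  # 1..3
                    up = _mutate(rng, up, up_subs)
                up_del = 0
                if rng.random() < er.p_up_deletion:
                    up_del = 1
                    p = rng.integers(0, len(up))
                    up = up[:p] + up[p + 1 :]
                obs_umi = umi
                umi_has_n = rng.random() < er.p_umi_N
                if umi_has_n:
                    p = rng.integers(0, UMI_LEN)
                    obs_umi = obs_umi[:p] + "N" + obs_umi[p + 1 :]
                bead_umi = "".join(ALPHABET[rng.integers(0, 4, BEAD_UMI_LEN - 2)])
                bead_umi += "".join(np.array(list("ACG"))[rng.integers(0, 3, 2)])
                seq2 = bc[:BC1_LEN] + up + bc[BC1_LEN:] + bead_umi
                if up_del:
                    seq2 += ALPHABET[rng.integers(0, 4)]  # fixed read length
                name = f"read{read_id}"
                r1.append((name, cell_bc + obs_umi))
                r2.append((name, seq2))
                log_rows.append(
                    (
                        name,
                        cell_bc,
                        umi,
                        bead_bcs[bead_idx],
                        bead_bcs[obs_bead],
                        umi_has_n,
                        up_subs,
                        up_del,
                        bc_subs,
                        chimera,
                    )
                )
                read_id += 1

    log = pd.DataFrame(
        log_rows,
        columns=[
            "read",
            "cell",
            "umi",
            "true_bead",
            "emitted_bead",
            "umi_has_N",
            "up_subs",
            "up_del",
            "bc_subs",
            "chimera",
        ],
    )
    return SpatialReadSet(r1=r1, r2=r2, log=log)


# ------------------------------------------------------------ homology table


def generate_ortholog_table(
    config: SimConfig,
    truth: SimTruth,
    n_one_to_many: int = 10,
    n_many_to_one: int = 10,
) -> pd.DataFrame:
    """Homology table in the MGI HOM report layout (class key, organism,
    symbol), containing the truth's strict one-to-one classes plus violating
    classes (2+ genes in one species, built from decoy symbols) that a
    downstream strict filter must reject."""
    rows = []
    key = 1
    for mg, hg in truth.ortholog_pairs:
        rows.append((key, MOUSE, mg))
        rows.append((key, HUMAN, hg))
        key += 1
    for i in range(n_one_to_many):
        rows.append((key, MOUSE, f"DecoyM{i:03d}"))
        rows.append((key, HUMAN, f"DECOYH{i:03d}a"))
        rows.append((key, HUMAN, f"DECOYH{i:03d}b"))
        key += 1
    for i in range(n_many_to_one):
        rows.append((key, MOUSE, f"DecoyM{i:03d}x"))
        rows.append((key, MOUSE, f"DecoyM{i:03d}y"))
        rows.append((key, HUMAN, f"DECOYH{i:03d}z"))
        key += 1
    return pd.DataFrame(
        rows, columns=["DB Class Key", "Common Organism Name", "Symbol"]
    )


# --------------------------------------------------- focused test scenarios


def generate_two_population_counts(
    n_per_type: int = 200,
    n_genes: int = 300,
    doublet_rate: float = 0.1,
    depth: float = 2000.0,
    nb_dispersion: float = 2.0,
    fold: float = 6.0,
    seed: int = 0,
) -> ad.AnnData:
    """Two well-separated cell populations with injected doublets.

    Each population upregulates its own disjoint third of the genes by
    ``fold``; doublets are sums of one cell from each population, so they
    sit between the two clusters. Ground truth in ``obs['true_doublet']``.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0.0, 1.0, n_genes)
    third = n_genes // 3
    prof_a = base.copy()
    prof_a[:third] *= fold
    prof_b = base.copy()
    prof_b[third : 2 * third] *= fold

    def draw(profile, n):
        mu = profile / profile.sum() * depth
        lam = rng.gamma(nb_dispersion, np.tile(mu / nb_dispersion, (n, 1)))
        return rng.poisson(lam).astype(np.int64)

    a = draw(prof_a, n_per_type)
    b = draw(prof_b, n_per_type)
    n_doub = int(round(doublet_rate * 2 * n_per_type))
    ia = rng.integers(0, n_per_type, n_doub)
    ib = rng.integers(0, n_per_type, n_doub)
    doub = a[ia] + b[ib]
    X = np.vstack([a, b, doub]).astype(np.float32)
    labels = np.zeros(X.shape[0], dtype=bool)
    labels[2 * n_per_type :] = True
    obs = pd.DataFrame(
        {"true_doublet": labels},
        index=pd.Index([f"cell{i:05d}" for i in range(X.shape[0])], name="cell"),
    )
    var = pd.DataFrame(
        {"mt": False},
        index=pd.Index([f"Gene{i:05d}" for i in range(n_genes)], name="gene"),
    )
    return ad.AnnData(X=X, obs=obs, var=var)


# ------------------------------------------------------------------ exports


def write_counts_10x(adata: ad.AnnData, out_dir: str | Path) -> None:
    """Write a 10x-style triplet directory: matrix.mtx, features.tsv,
    barcodes.tsv (uncompressed, genes x cells orientation)."""
    from scipy import io as sio
    from scipy import sparse

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = sparse.csr_matrix(adata.X)
    sio.mmwrite(str(out / "matrix.mtx"), X.T.astype(np.int64))
    feats = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "gene_name": adata.var_names,
            "feature_type": "Gene Expression",
        }
    )
    feats.to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        out / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_counts_10x(in_dir: str | Path) -> ad.AnnData:
    """Read a 10x-style triplet directory written by :func:`write_counts_10x`."""
    import scanpy as sc

    adata = sc.read_mtx(str(Path(in_dir) / "matrix.mtx")).T
    feats = pd.read_csv(Path(in_dir) / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(Path(in_dir) / "barcodes.tsv", sep="\t", header=None)
    adata.var_names = feats[0].astype(str).tolist()
    adata.obs_names = barcodes[0].astype(str).tolist()
    adata.var["mt"] = pd.Index(adata.var_names).str.upper().str.startswith("MT-")
    return adata
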