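"""Spatial-barcode read parsing and DBSCAN-based cell placement.

Reads are filtered in order: (1) no 'N' in the library UMI; (2) the
universal-primer (UP) linker is detectable, permitting one deletion or up
to two substitutions; (3) the concatenated 15-nt spatial barcode matches
the bead whitelist exactly or through a unique one-substitution /
one-deletion rescue; (4) the cell barcode belongs to the called-cell set;
(5) chimeric (cell, UMI) groups spanning several beads are resolved by a
dominant-bead rule. Survivors are collapsed to UMI counts per (cell, bead).

Each cell's beads are then classified into signal vs noise with DBSCAN
(UMI counts act as point weights for the density condition), the (eps,
minPts) pair is chosen from a candidate grid by a placement score, and
cells with exactly one signal cluster receive its UMI-weighted centroid.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .config import ChimeraParams, DbscanParams
from .simulate import BC1_LEN, BC2_LEN, CELL_BC_LEN, UMI_LEN, UP_SEQ

UP_OFFSET = BC1_LEN        # expected UP start in R2
UP_SCAN = 2                # scan +/- this many nt around the expected start


# -------------------------------------------------------------- UP matching


def _hamming(a: str, b: str) -> int:
    return sum(c1 != c2 for c1, c2 in zip(a, b))


def _matches_one_deletion(read17: str, up: str = UP_SEQ) -> bool:
    """True if read17 equals ``up`` with exactly one base deleted (no
    substitutions). Longest-common-prefix/suffix check, O(len)."""
    if len(read17) != len(up) - 1:
        return False
    i = 0
    while i < len(read17) and read17[i] == up[i]:
        i += 1
    j = 0
    while j < len(read17) - i and read17[-1 - j] == up[-1 - j]:
        j += 1
    return i + j >= len(read17)


def find_up_site(seq: str, expected_offset: int = UP_OFFSET, scan: int = UP_SCAN):
    """Locate the UP linker allowing <=2 substitutions or exactly one
    deletion, scanning offsets around the expected start (ties resolved
    toward the expected offset, then toward substitutions over deletion).

    Returns (offset, up_len) or None.
    """
    offsets = sorted(
        range(max(0, expected_offset - scan), expected_offset + scan + 1),
        key=lambda o: (abs(o - expected_offset), o),
    )
    best = None  # (mismatches, rank) -> offset
    for rank, off in enumerate(offsets):
        window = seq[off : off + len(UP_SEQ)]
        if len(window) == len(UP_SEQ):
            d = _hamming(window, UP_SEQ)
            if d <= 2 and (best is None or d < best[0]):
                best = (d, off, len(UP_SEQ))
                if d == 0:
                    return off, len(UP_SEQ)
    if best is not None:
        return best[1], best[2]
    for off in offsets:
        window = seq[off : off + len(UP_SEQ) - 1]
        if _matches_one_deletion(window):
            return off, len(UP_SEQ) - 1
    return None


# --------------------------------------------------------- whitelist lookup


class WhitelistMatcher:
    """Exact / unique-1-substitution / unique-1-deletion barcode matching.

    Ambiguous rescues (two or more whitelist candidates) reject the read;
    an ambiguous rescue would corrupt placement.
    """

    def __init__(self, barcodes: Iterable[str]):
        self.exact = set(barcodes)
        if not self.exact:
            raise ValueError("whitelist is empty")
        lens = {len(b) for b in self.exact}
        if len(lens) != 1:
            raise ValueError("whitelist barcodes must share one length")
        self.length = lens.pop()
        self.deletions: dict[str, Optional[str]] = {}
        for bc in self.exact:
            for i in range(self.length):
                d = bc[:i] + bc[i + 1 :]
                prev = self.deletions.get(d, bc)
                # None marks a variant reachable from two different barcodes
                self.deletions[d] = bc if prev == bc else None

    def match(self, query: str) -> Optional[str]:
        if query in self.exact:
            return query
        if len(query) == self.length:
            hit = None
            for i in range(self.length):
                for b in "ACGT":
                    if b == query[i]:
                        continue
                    cand = query[:i] + b + query[i + 1 :]
                    if cand in self.exact:
                        if hit is not None and cand != hit:
                            return None  # ambiguous
                        hit = cand
            return hit
        if len(query) == self.length - 1:
            return self.deletions.get(query)
        return None


# ------------------------------------------------------------- read parsing


@dataclass
class BarcodeCountMatrix:
    """UMI counts per (cell barcode, spatial barcode) with filter provenance."""

    counts: pd.DataFrame          # columns: cell, bead, numi
    provenance: dict = field(default_factory=dict)


def _iter_fastq(path: str | Path):
    """Yield (name, seq) from a FASTQ file, raising on malformed records."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        it = FastqGeneralIterator(fh)
        idx = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {idx} in {path}: {exc}")
            yield rec[0], rec[1]
            idx += 1


def parse_spatial_reads(
    r1: str | Path | list[tuple[str, str]],
    r2: str | Path | list[tuple[str, str]],
    whitelist: pd.DataFrame,
    called_cells: Iterable[str],
    chimera: ChimeraParams | None = None,
) -> BarcodeCountMatrix:
    """Filter read pairs and collapse survivors into a spatial barcode
    count matrix.

    ``r1``/``r2`` may be FASTQ paths or in-memory (name, seq) lists.
    Returns UMI counts per (cell, bead) plus per-filter loss tallies under
    ``provenance``.
    """
    chimera = chimera or ChimeraParams()
    called = set(called_cells)
    if not called:
        raise ValueError("called_cells is empty")
    matcher = WhitelistMatcher(whitelist["barcode"])

    reads1 = r1 if isinstance(r1, list) else _iter_fastq(r1)
    reads2 = r2 if isinstance(r2, list) else _iter_fastq(r2)

    tally = {
        "total": 0,
        "umi_N": 0,
        "no_up": 0,
        "no_whitelist": 0,
        "not_called": 0,
        "chimeric": 0,
        "pass": 0,
    }
    groups: dict[tuple[str, str], dict[str, int]] = {}
    for (n1, seq1), (n2, seq2) in zip(reads1, reads2, strict=True):
        if n1.split()[0] != n2.split()[0]:
            raise ValueError(f"read-pair name mismatch: {n1!r} vs {n2!r}")
        tally["total"] += 1
        cell = seq1[:CELL_BC_LEN]
        umi = seq1[CELL_BC_LEN : CELL_BC_LEN + UMI_LEN]
        if "N" in umi:
            tally["umi_N"] += 1
            continue
        hit = find_up_site(seq2)
        if hit is None:
            tally["no_up"] += 1
            continue
        off, up_len = hit
        bc = seq2[:off] + seq2[off + up_len : off + up_len + BC2_LEN]
        bead = matcher.match(bc)
        if bead is None:
            tally["no_whitelist"] += 1
            continue
        if cell not in called:
            tally["not_called"] += 1
            continue
        groups.setdefault((cell, umi), {})
        groups[(cell, umi)][bead] = groups[(cell, umi)].get(bead, 0) + 1

    # chimera rule per (cell, UMI), then collapse to UMI counts
    counts: dict[tuple[str, str], int] = {}
    for (cell, umi), beads in groups.items():
        total = sum(beads.values())
        top_bead, top_n = max(beads.items(), key=lambda kv: (kv[1], kv[0]))
        if len(beads) > 1 and top_n < chimera.top_frac * total:
            tally["chimeric"] += total
            continue
        tally["pass"] += total
        counts[(cell, top_bead)] = counts.get((cell, top_bead), 0) + 1

    df = pd.DataFrame(
        [(c, b, n) for (c, b), n in sorted(counts.items())],
        columns=["cell", "bead", "numi"],
    )
    return BarcodeCountMatrix(counts=df, provenance=tally)


# -------------------------------------------------------------- positioning


def _default_eps_grid(coords: np.ndarray) -> tuple[float, ...]:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(coords).query(coords, k=2)
    spacing = float(np.median(d[:, 1]))
    return tuple(spacing * m for m in (1.5, 2.5, 4.0, 6.0))


def _cluster_cell(xy, w, eps, min_pts):
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit(xy, sample_weight=w).labels_
    return labels


def assign_positions(
    matrix: BarcodeCountMatrix,
    whitelist: pd.DataFrame,
    params: DbscanParams | None = None,
) -> pd.DataFrame:
    """Place each cell at the UMI-weighted centroid of its single signal
    cluster; cells with zero or multiple signal clusters stay unplaced.

    (eps, minPts) are selected from the candidate grids by the placement
    score: the fraction of cells whose DBSCAN run yields exactly one signal
    cluster holding at least half of the cell's UMIs. Ties prefer smaller
    eps. UMI counts enter DBSCAN as sample weights, so a bead with nUMI=n
    counts n times toward the core-point density condition.
    """
    params = params or DbscanParams()
    if matrix.counts.empty:
        raise ValueError("barcode count matrix is empty")
    wl = whitelist.set_index("barcode")[["x", "y"]]
    merged = matrix.counts.join(wl, on="bead", how="inner")
    cells = []
    for cell, grp in merged.groupby("cell", sort=True):
        cells.append(
            (cell, grp[["x", "y"]].to_numpy(float), grp["numi"].to_numpy(float))
        )

    eps_grid = params.eps_grid or _default_eps_grid(wl.to_numpy(float))
    best = None  # (score, -eps) maximized
    for min_pts in params.min_pts_grid:
        for eps in eps_grid:
            good = 0
            for _, xy, w in cells:
                labels = _cluster_cell(xy, w, eps, min_pts)
                sig = [l for l in np.unique(labels) if l >= 0]
                if len(sig) == 1:
                    frac = w[labels == sig[0]].sum() / w.sum()
                    if frac >= params.min_cluster_umi_frac:
                        good += 1
            score = good / len(cells)
            key = (score, -eps)
            if best is None or key > best[0]:
                best = (key, eps, min_pts)
    _, eps, min_pts = best

    rows = []
    for cell, xy, w in cells:
        labels = _cluster_cell(xy, w, eps, min_pts)
        sig = [l for l in np.unique(labels) if l >= 0]
        if len(sig) == 1:
            mask = labels == sig[0]
            cx = float(np.average(xy[mask, 0], weights=w[mask]))
            cy = float(np.average(xy[mask, 1], weights=w[mask]))
            rows.append((cell, True, cx, cy, int(w[mask].sum()), 1))
        else:
            rows.append((cell, False, np.nan, np.nan, 0, len(sig)))
    out = pd.DataFrame(
        rows, columns=["cell", "placed", "x", "y", "n_signal_umis", "n_clusters_found"]
    )
    out.attrs["eps"] = eps
    out.attrs["min_pts"] = min_pts
    return out
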