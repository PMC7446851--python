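"""Localized element-specific topological features for nucleotide flexibility.

For every sample atom (the ribose C1' of each nucleotide) a local region of
cutoff radius E (Å) is carved out of the chain's heavy atoms, split by
element into C/N/O/P point clouds (the central C1' is always part of every
cloud), and each cloud is summarized by Vietoris–Rips persistence barcodes
over the filtration interval [0, F] with F = E * (F/E ratio).

Each barcode is vectorized by binning: the interval [0, F] carries N grid
points k*F/N (k = 1..N, N = round(F/f) for bin size f), and component k
counts the bars (b, d) with b <= k*F/N <= d, both ends inclusive, an
infinite death satisfying the right inequality everywhere.  The per-element,
per-dimension count vectors are concatenated element-major (fixed order
C, N, O, P), dimension-minor (ascending), giving an integer feature vector
of length |elements| * |dims| * N per nucleotide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .persistence import Barcode, FiltrationConfig, PointCloud, rips_persistence
from .structure import Atom, StructureSet, find_sample_atoms, select_heavy_atoms
from .targets import MODIFIED_Z_THRESHOLD, normalize_bfactors, remove_outliers_median

__all__ = [
    "FeatureConfig",
    "SampleFeature",
    "Dataset",
    "extract_local_region",
    "bin_barcode",
    "featurize_sample",
    "build_dataset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureConfig:
    """Featurization hyperparameters.

    Parameters
    ----------
    cutoff : float
        Local-region radius E in Å.
    fe_ratio : float
        Ratio F/E in (0, 1]; the filtration interval is [0, E * fe_ratio].
    bin_size : float
        Nominal bin width f in Å.  The bin count is N = round(F / f)
        (at least 1) and the effective width F/N must stay within 25% of f.
    elements : tuple of str
        Ordered subset of (C, N, O, P).
    dims : tuple of int
        Homology dimensions, ascending subset of (0, 1, 2).
    """

    cutoff: float = 15.0
    fe_ratio: float = 0.5
    bin_size: float = 0.5
    elements: tuple = ("C", "N", "O", "P")
    dims: tuple = (0, 1)
    outlier_threshold: float = MODIFIED_Z_THRESHOLD

    def __post_init__(self) -> None:
        if not (self.cutoff > 0):
            raise ValueError("cutoff E must be positive")
        if not (0 < self.fe_ratio <= 1):
            raise ValueError("fe_ratio must lie in (0, 1]")
        if not (self.bin_size > 0):
            raise ValueError("bin_size must be positive")
        order = {"C": 0, "N": 1, "O": 2, "P": 3}
        if not self.elements or any(e not in order for e in self.elements):
            raise ValueError("elements must be a non-empty subset of C,N,O,P")
        if list(self.elements) != sorted(set(self.elements), key=order.get):
            raise ValueError("elements must be unique and in C,N,O,P order")
        if not self.dims or any(d not in (0, 1, 2) for d in self.dims):
            raise ValueError("dims must be a non-empty subset of {0,1,2}")
        if list(self.dims) != sorted(set(self.dims)):
            raise ValueError("dims must be unique and ascending")
        eff = self.max_filtration / self.n_bins
        if abs(eff - self.bin_size) > 0.25 * self.bin_size:
            raise ValueError(
                f"effective bin width {eff:.4g} deviates more than 25% from "
                f"bin_size {self.bin_size:.4g}"
            )

    @property
    def max_filtration(self) -> float:
        """F = E * (F/E)."""
        return self.cutoff * self.fe_ratio

    @property
    def n_bins(self) -> int:
        """N = round(F/f), at least 1."""
        return max(1, round(self.max_filtration / self.bin_size))

    @property
    def n_features(self) -> int:
        """p = |elements| * |dims| * N."""
        return len(self.elements) * len(self.dims) * self.n_bins

    def feature_names(self) -> list[str]:
        return [
            f"{el}_dim{d}_bin{k}"
            for el in self.elements
            for d in self.dims
            for k in range(1, self.n_bins + 1)
        ]

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "fe_ratio": self.fe_ratio,
            "bin_size": self.bin_size,
            "elements": list(self.elements),
            "dims": list(self.dims),
            "outlier_threshold": self.outlier_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        d = dict(d)
        d["elements"] = tuple(d.get("elements", ("C", "N", "O", "P")))
        d["dims"] = tuple(d.get("dims", (0, 1)))
        return cls(**d)


@dataclass(frozen=True)
class SampleFeature:
    """Feature vector and target of one nucleotide."""

    sample_id: tuple  # (chain_id, residue_index)
    x: np.ndarray  # non-negative integer counts, length n_features
    y: float  # normalized B-factor


@dataclass
class Dataset:
    """Feature matrix, targets and chain labels for learning."""

    X: np.ndarray
    y: np.ndarray
    chain_labels: np.ndarray
    sample_ids: list
    config: FeatureConfig

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.y) == len(self.chain_labels) == len(self.sample_ids) == n):
            raise ValueError("X rows, y, chain_labels and sample_ids must align")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def chains(self) -> list:
        """Unique chain labels in first-appearance order."""
        seen: dict = {}
        for c in self.chain_labels:
            seen.setdefault(c, None)
        return list(seen)

    def subset_chains(self, chains: Sequence) -> "Dataset":
        wanted = set(chains)
        mask = np.array([c in wanted for c in self.chain_labels])
        return Dataset(
            self.X[mask],
            self.y[mask],
            self.chain_labels[mask],
            [s for s, m in zip(self.sample_ids, mask) if m],
            self.config,
        )

    def to_csv(self, path) -> None:
        """Write the dataset as CSV plus a YAML config sidecar."""
        path = Path(path)
        df = pd.DataFrame(self.X, columns=self.config.feature_names())
        df.insert(0, "sample_id", ["/".join(map(str, s)) for s in self.sample_ids])
        df.insert(1, "chain_id", self.chain_labels)
        df.insert(2, "y", self.y)
        df.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.yaml")
        sidecar.write_text(yaml.safe_dump({"feature_config": self.config.to_dict()}))

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".meta.yaml")
        if sidecar.is_file():
            cfg = FeatureConfig.from_dict(
                yaml.safe_load(sidecar.read_text())["feature_config"]
            )
        else:
            raise FileNotFoundError(f"missing config sidecar {sidecar}")
        meta = ["sample_id", "chain_id", "y"]
        feat_cols = [c for c in df.columns if c not in meta]
        if feat_cols != cfg.feature_names():
            raise ValueError("CSV feature columns do not match the sidecar config")
        sample_ids = [tuple(s.split("/")) for s in df["sample_id"]]
        return cls(
            df[feat_cols].to_numpy(dtype=np.int64),
            df["y"].to_numpy(dtype=float),
            df["chain_id"].to_numpy(),
            sample_ids,
            cfg,
        )


def extract_local_region(
    heavy_atoms: Sequence[Atom], center: Atom, cutoff: float, element: str
) -> PointCloud:
    """Coordinates of ``element`` atoms within ``cutoff`` Å of ``center``.

    The central atom's own coordinates are always part of the cloud (it is a
    carbon, so for element C it is simply not duplicated).
    """
    if not (cutoff > 0):
        raise ValueError("cutoff must be positive")
    matching = [a.coords for a in heavy_atoms
                if a.element == element and a is not center]
    if matching:
        coords = np.asarray(matching)
        near = np.linalg.norm(coords - center.coords, axis=1) <= cutoff
        pts = np.vstack([coords[near], center.coords[None, :]])
    else:
        pts = center.coords[None, :]
    return PointCloud(pts, label=((center.chain_id, center.residue_index), element))


def bin_barcode(barcode: Barcode, max_filtration: float, n_bins: int) -> np.ndarray:
    """Counts of bars alive at each grid point k*F/N, k = 1..N.

    Comparisons are inclusive at both ends; an infinite death keeps the bar
    alive at every grid point at or after its birth.
    """
    if not (max_filtration > 0) or n_bins < 1:
        raise ValueError("need F > 0 and N >= 1")
    out = np.zeros(n_bins, dtype=np.int64)
    for bar in barcode.bars:
        for k in range(1, n_bins + 1):
            t = k * max_filtration / n_bins
            if bar.birth <= t <= bar.death:
                out[k - 1] += 1
    return out


def featurize_sample(
    heavy_atoms: Sequence[Atom], center: Atom, cfg: FeatureConfig
) -> np.ndarray:
    """Concatenated per-element, per-dimension binned barcode counts."""
    F, N = cfg.max_filtration, cfg.n_bins
    filt = FiltrationConfig(F, max_dim=max(cfg.dims))
    blocks: list[np.ndarray] = []
    for el in cfg.elements:
        cloud = extract_local_region(heavy_atoms, center, cfg.cutoff, el)
        if len(cloud) == 1 and max(cfg.dims) >= 1:
            logger.debug(
                "sample %s element %s: single-point cloud, higher-dim blocks zero",
                cloud.label[0], el,
            )
        barcodes = rips_persistence(cloud, filt)
        for d in cfg.dims:
            blocks.append(bin_barcode(barcodes[d], F, N))
    return np.concatenate(blocks)


def build_dataset(structures: StructureSet, cfg: FeatureConfig) -> Dataset:
    """Featurize every usable chain of a structure set.

    Per chain: locate the sample atoms, drop B-factor outliers with the
    median rule, z-normalize the retained B-factors, then featurize each
    retained nucleotide.  Chains with fewer than 3 sample atoms, with no
    sample atoms at all, or with zero B-factor variance are skipped with a
    warning.  Raises if no chain is usable.
    """
    rows: list[np.ndarray] = []
    ys: list[float] = []
    labels: list = []
    sample_ids: list = []
    for chain in structures.chains:
        samples = find_sample_atoms(chain)
        if len(samples) < 3:
            logger.warning(
                "chain %s: %d sample atoms (< 3), skipped", chain.chain_id, len(samples)
            )
            continue
        raw_b = np.array([a.b_factor for a in samples], dtype=float)
        mask = remove_outliers_median(raw_b, cfg.outlier_threshold)
        kept = [a for a, m in zip(samples, mask) if m]
        if len(kept) < 2:
            logger.warning("chain %s: fewer than 2 retained samples, skipped",
                           chain.chain_id)
            continue
        try:
            y = normalize_bfactors(raw_b[mask])
        except ValueError as exc:
            logger.warning("chain %s skipped: %s", chain.chain_id, exc)
            continue
        heavy = select_heavy_atoms(chain)
        for atom, target in zip(kept, y):
            rows.append(featurize_sample(heavy, atom, cfg))
            ys.append(float(target))
            labels.append(chain.chain_id)
            sample_ids.append((atom.chain_id, atom.residue_index))
    if not rows:
        raise ValueError("no usable chains: cannot build a dataset")
    return Dataset(
        np.vstack(rows).astype(np.int64),
        np.array(ys),
        np.array(labels),
        sample_ids,
        cfg,
    )
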