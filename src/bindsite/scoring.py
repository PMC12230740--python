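"""Site-level feature aggregation, accessibility clusters and functional score.

Residue features (RSA, divergence DS, missense enrichment MES) are
averaged over the residues of each binding site. The mean burial of a
site places it in one of four accessibility clusters C1-C4, ordered from
most buried (C1) to most exposed (C4); cluster membership is expressed
as a probability vector P. The functional score is the dot product

    FS = P . F,      F = [0.52, 0.18, 0.05, 0.04]

where f_j is the proportion of annotated functional sites observed in
cluster j, so FS estimates the probability that the site is functional
and ranges from 0.04 (certainly C4) to 0.52 (certainly C1).

The production classifier behind P (a trained multilayer perceptron) is
not redistributable; the default model here is a transparent
centroid-softmax stand-in over (mean RSA, RSA interquartile range) with
centroids at 15/40/65/90 % RSA, plus a plug-in interface for any
user-trained classifier exposing ``predict_proba``-style behaviour.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .sites import BindingSite

__all__ = [
    "FunctionalProportions",
    "SiteFeatures",
    "ResidueFeatures",
    "ClusterModel",
    "CentroidSoftmaxModel",
    "aggregate_site_features",
    "cluster_probabilities",
    "functional_score",
    "rank_sites",
    "score_sites",
]

CLUSTER_LABELS = ("C1", "C2", "C3", "C4")


@dataclass(frozen=True)
class FunctionalProportions:
    """Proportion of annotated functional sites per accessibility cluster."""

    F: tuple[float, float, float, float] = (0.52, 0.18, 0.05, 0.04)

    def __post_init__(self) -> None:
        if len(self.F) != 4 or not all(0.0 <= f <= 1.0 for f in self.F):
            raise ValueError("F must be four proportions in [0, 1]")


@dataclass
class ResidueFeatures:
    """Per-residue characterisation row (reference numbering)."""

    reference_index: int
    aa: str = ""
    msa_column: int | None = None
    DS: float | None = None
    MES: float | None = None
    p: float | None = None
    RSA: float | None = None
    SS: str | None = None


@dataclass
class SiteFeatures:
    site_id: int
    size: int
    mean_RSA: float | None
    mean_DS: float | None
    mean_MES: float | None
    rsa_iqr: float | None = None
    P: tuple[float, float, float, float] | None = None
    cluster_label: str | None = None
    FS: float | None = None
    n_ligands: int | None = None


class ClusterModel:
    """Interface for accessibility-cluster classifiers."""

    def predict_proba(self, features: SiteFeatures) -> np.ndarray:
        raise NotImplementedError


@dataclass
class CentroidSoftmaxModel(ClusterModel):
    """Softmax over negative squared distances to four cluster centroids.

    Features are (mean RSA, RSA interquartile range); centroids are
    ordered buried -> exposed so that C1 is the most buried cluster. The
    temperature sets how sharply probability concentrates on the nearest
    centroid (units of squared RSA percent).
    """

    centroids: tuple[tuple[float, float], ...] = (
        (15.0, 15.0), (40.0, 15.0), (65.0, 15.0), (90.0, 15.0))
    temperature: float = 50.0
    use_iqr: bool = True

    def __post_init__(self) -> None:
        if len(self.centroids) != 4:
            raise ValueError("exactly four centroids (C1..C4) are required")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def predict_proba(self, features: SiteFeatures) -> np.ndarray:
        if features.mean_RSA is None:
            raise ValueError("mean RSA undefined; cannot assign clusters")
        x = np.array([features.mean_RSA,
                      features.rsa_iqr if (self.use_iqr and features.rsa_iqr is not None)
                      else 0.0])
        d2 = []
        for cx, cy in self.centroids:
            cy_eff = cy if (self.use_iqr and features.rsa_iqr is not None) else 0.0
            d2.append((x[0] - cx) ** 2 + (x[1] - cy_eff) ** 2)
        logits = -np.array(d2) / self.temperature
        logits -= logits.max()
        w = np.exp(logits)
        return w / w.sum()

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "model": "centroid-softmax", "version": 1,
            "centroids": [list(c) for c in self.centroids],
            "temperature": self.temperature,
            "use_iqr": self.use_iqr,
        }, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CentroidSoftmaxModel":
        data = json.loads(Path(path).read_text())
        if data.get("model") != "centroid-softmax":
            raise ValueError(f"not a centroid-softmax model file: {path}")
        return cls(centroids=tuple(tuple(c) for c in data["centroids"]),
                   temperature=float(data["temperature"]),
                   use_iqr=bool(data.get("use_iqr", True)))


def _mean(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


def aggregate_site_features(site: BindingSite,
                            residue_features: Mapping[int, ResidueFeatures],
                            ) -> SiteFeatures:
    """Arithmetic means of residue features over a site's residues.

    Residues with an undefined value are excluded from that feature's
    mean; a feature with no defined residue values is left undefined
    (mean MES in particular, for alignments without human homologues).
    Every residue must have an RSA value.
    """
    if not site.residues:
        raise ValueError(f"site {site.site_id} has an empty residue set")
    rsa, ds, mes = [], [], []
    for idx in sorted(site.residues):
        feat = residue_features.get(idx)
        if feat is None:
            continue
        if feat.RSA is not None:
            rsa.append(feat.RSA)
        if feat.DS is not None:
            ds.append(feat.DS)
        if feat.MES is not None:
            mes.append(feat.MES)
    if not rsa:
        raise ValueError(f"site {site.site_id}: no residue has an RSA value")
    q75, q25 = np.percentile(rsa, [75, 25])
    return SiteFeatures(
        site_id=site.site_id,
        size=len(site.residues),
        mean_RSA=_mean(rsa),
        mean_DS=_mean(ds),
        mean_MES=_mean(mes),
        rsa_iqr=float(q75 - q25),
    )


def cluster_probabilities(features: SiteFeatures,
                          model: ClusterModel | None = None) -> np.ndarray:
    """Cluster-membership probability vector P for one site."""
    if model is None:
        raise ValueError("a cluster model is required")
    p = np.asarray(model.predict_proba(features), dtype=float)
    if p.shape != (4,) or np.any(p < -1e-12):
        raise ValueError("cluster model must return four non-negative probabilities")
    total = p.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"cluster probabilities sum to {total}, expected 1")
    return p / total


def functional_score(P: Sequence[float],
                     F: FunctionalProportions | Sequence[float] = FunctionalProportions(),
                     ) -> float:
    """FS = sum_j p_j * f_j, the P.F dot product."""
    p = np.asarray(P, dtype=float)
    f = np.asarray(F.F if isinstance(F, FunctionalProportions) else F, dtype=float)
    if p.shape != (4,) or f.shape != (4,):
        raise ValueError("P and F must be 4-vectors")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"P must sum to 1 (got {p.sum()!r})")
    if np.any(p < -1e-12):
        raise ValueError("P must be non-negative")
    return float(p @ f)


def score_sites(sites: Sequence[BindingSite],
                residue_features: Mapping[int, ResidueFeatures],
                model: ClusterModel | None = None,
                F: FunctionalProportions = FunctionalProportions(),
                ) -> list[SiteFeatures]:
    """Aggregate, cluster and score every site; attaches SiteFeatures."""
    if model is None:
        model = CentroidSoftmaxModel()
    out = []
    for site in sites:
        feats = aggregate_site_features(site, residue_features)
        p = cluster_probabilities(feats, model)
        feats.P = tuple(float(x) for x in p)
        feats.cluster_label = CLUSTER_LABELS[int(np.argmax(p))]
        feats.FS = functional_score(p, F)
        site.features = feats
        out.append(feats)
    return out


_DESCENDING_KEYS = {"FS", "size"}


def rank_sites(features: Sequence[SiteFeatures], key: str = "FS") -> list[SiteFeatures]:
    """Stable ranking of sites by one feature.

    FS and size rank descending (high first); mean_DS and mean_MES rank
    ascending (conserved / depleted first). Sites with the key undefined
    are placed last, keeping their site_id order.
    """
    if key not in {"FS", "size", "mean_DS", "mean_MES", "mean_RSA"}:
        raise ValueError(f"unknown ranking key {key!r}")
    descending = key in _DESCENDING_KEYS

    def sort_key(f: SiteFeatures):
        value = getattr(f, key)
        if value is None:
            return (1, 0.0)
        return (0, -value if descending else value)

    return sorted(features, key=sort_key)
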