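"""Automated spectral classification: decision tree screening + MESMA unmixing.

The automated branch works pixel-by-pixel in two stages.  A binary decision
tree over the six reflectance bands plus NDVI screens candidate kelp pixels
from the surrounding water.  Each candidate is then unmixed with Multiple
Endmember Spectral Mixture Analysis (MESMA): its spectrum is modeled as a
two-endmember linear mixture ``f * kelp + (1 - f) * water`` for every water
endmember in a per-scene library, and the model with the lowest spectral
reconstruction RMSE supplies the fractional kelp cover ``f``.  Fractions are
binarized at 13% to produce presence/absence maps.

The water endmembers are sampled from offshore pixels of the scene itself;
the single kelp endmember is fixed a priori.  ``f`` is left unconstrained
(it can be negative or exceed 1), which is what makes the downstream
over-range (>300%) filter meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .geo_core import BANDS, BinaryCanopyMap, DistanceField, Grid, Scene

__all__ = [
    "KELP_ENDMEMBER",
    "EndmemberLibrary",
    "FractionalCoverageMap",
    "DecisionTreeModel",
    "extract_water_endmembers",
    "train_decision_tree",
    "apply_decision_tree",
    "default_rule_tree",
    "mesma_unmix",
    "mesma_unmix_many",
    "classify_scene",
]

#: A priori kelp canopy endmember (blue, green, red, nir, swir1, swir2).
#: Floating kelp is NIR-bright and red-absorbing; these reflectances are
#: fixture constants with realistic shape, not measurements.
KELP_ENDMEMBER = np.array([0.030, 0.060, 0.032, 0.300, 0.080, 0.040])

FEATURE_NAMES = list(BANDS) + ["ndvi"]

#: Fractional-cover threshold for presence/absence conversion (13%, inclusive).
DEFAULT_FRACTION_THRESHOLD = 0.13


@dataclass
class EndmemberLibrary:
    """One a-priori kelp endmember plus per-scene water endmembers."""

    kelp: np.ndarray
    water: np.ndarray  # (n_water, 6)
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.kelp = np.asarray(self.kelp, dtype=float).reshape(-1)
        self.water = np.atleast_2d(np.asarray(self.water, dtype=float))
        if self.kelp.shape != (len(BANDS),):
            raise ValueError("kelp endmember must have 6 bands")
        if self.water.shape[0] < 1 or self.water.shape[1] != len(BANDS):
            raise ValueError("need at least one 6-band water endmember")
        if not (np.all(np.isfinite(self.kelp)) and np.all(np.isfinite(self.water))):
            raise ValueError("endmember spectra must be finite")
        if not self.ids:
            self.ids = [f"water_{i}" for i in range(self.water.shape[0])]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = [{"id": "kelp", "role": "kelp", **dict(zip(BANDS, self.kelp))}]
        for i, w in enumerate(self.water):
            rows.append({"id": self.ids[i], "role": "water", **dict(zip(BANDS, w))})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EndmemberLibrary":
        import pandas as pd

        df = pd.read_csv(path)
        kelp = df[df.role == "kelp"][list(BANDS)].to_numpy()[0]
        water_df = df[df.role == "water"]
        return cls(kelp=kelp, water=water_df[list(BANDS)].to_numpy(),
                   ids=list(water_df["id"]))


@dataclass
class FractionalCoverageMap:
    """Per-pixel fractional kelp cover from MESMA.

    ``fraction`` is defined (non-NaN) only where ``candidate_mask`` is true;
    it is unconstrained real — values above 3.0 are physically implausible
    and are removed later by the over-range filter, not here.
    """

    grid: Grid
    fraction: np.ndarray
    fit_rmse: np.ndarray
    candidate_mask: np.ndarray

    def __post_init__(self) -> None:
        for name in ("fraction", "fit_rmse", "candidate_mask"):
            if getattr(self, name).shape != self.grid.shape:
                raise ValueError(f"{name} shape does not match grid")
        rmse = self.fit_rmse[~np.isnan(self.fit_rmse)]
        if rmse.size and rmse.min() < 0:
            raise ValueError("fit_rmse must be non-negative")


# ---------------------------------------------------------------------------
# decision tree


@dataclass
class DecisionTreeModel:
    """A trained CART screen over (6 bands + NDVI), or a fixed fallback rule.

    The fallback (``kind='rule'``) needs no training data: a pixel is a kelp
    candidate when NDVI > 0 and its NIR reflectance exceeds twice the scene's
    median offshore NIR.
    """

    kind: str  # 'cart' | 'rule'
    tree: DecisionTreeClassifier | None = None
    max_depth: int | None = None
    n_train: dict | None = None
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        if self.kind == "rule":
            Path(path).write_text(json.dumps({"kind": "rule"}))
            return
        t = self.tree.tree_
        doc = {
            "kind": "cart",
            "max_depth": self.max_depth,
            "seed": self.seed,
            "n_train": self.n_train,
            "features": FEATURE_NAMES,
            "nodes": [
                {
                    "feature": int(t.feature[i]),
                    "threshold": float(t.threshold[i]),
                    "left": int(t.children_left[i]),
                    "right": int(t.children_right[i]),
                    "value": t.value[i].tolist(),
                }
                for i in range(t.node_count)
            ],
        }
        Path(path).write_text(json.dumps(doc))


def _scene_features(scene: Scene) -> np.ndarray:
    feats = [scene.reflectance[i].ravel() for i in range(len(BANDS))]
    feats.append(scene.ndvi().ravel())
    return np.column_stack(feats)


def train_decision_tree(
    samples: np.ndarray,
    labels: np.ndarray,
    max_depth: int = 5,
    seed: int = 0,
) -> DecisionTreeModel:
    """Fit a CART (Gini impurity, greedy splits) kelp-candidate screen.

    ``samples`` are feature vectors (6 bands + NDVI); ``labels`` are boolean
    (kelp-candidate / not).  Both classes must be present.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("training data must contain both classes")
    clf = DecisionTreeClassifier(criterion="gini", max_depth=max_depth,
                                 random_state=seed)
    clf.fit(np.asarray(samples, dtype=float), labels)
    return DecisionTreeModel(
        kind="cart", tree=clf, max_depth=max_depth, seed=seed,
        n_train={"kelp": int(labels.sum()), "other": int((~labels).sum())},
    )


def default_rule_tree() -> DecisionTreeModel:
    """Fixed no-training screen: NDVI > 0 and NIR > 2x median offshore NIR."""
    return DecisionTreeModel(kind="rule")


def apply_decision_tree(
    model: DecisionTreeModel,
    scene: Scene,
    distance: DistanceField | None = None,
) -> np.ndarray:
    """Return the boolean kelp-candidate mask; land/cloud pixels are always False.

    The fixed rule needs the scene's offshore NIR statistics; ``distance``
    (when given) restricts "offshore" to > 1 km from the coast, otherwise all
    ocean pixels are used.
    """
    ocean = scene.ocean_mask
    if model.kind == "rule":
        nir = scene.band("nir")
        offshore = ocean if distance is None else (ocean & (distance.distance > 1000.0))
        ref = np.median(nir[offshore]) if offshore.any() else np.median(nir[ocean]) if ocean.any() else 0.0
        mask = (scene.ndvi() > 0) & (nir > 2.0 * ref)
    else:
        pred = model.tree.predict(_scene_features(scene)).reshape(scene.grid.shape)
        mask = pred.astype(bool)
    return mask & ocean


# ---------------------------------------------------------------------------
# water endmember extraction


def extract_water_endmembers(
    scene: Scene,
    distance: DistanceField,
    n: int = 30,
    seed: int = 0,
    offshore_min_m: float = 1000.0,
    glint_percentile: float = 95.0,
    exclude_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Sample ``n`` offshore water spectra from the scene as endmembers.

    Eligible pixels are unmasked ocean more than 1 km from the coastline.
    NIR-bright outliers (above the 95th percentile of offshore NIR — sun
    glint, whitecaps) are excluded before sampling so the water library is
    not contaminated with the very confusers MESMA is meant to separate.
    When the decision-tree screen has already run, pass its candidate mask
    as ``exclude_mask`` so offshore kelp itself cannot leak into the water
    library (a kelp-contaminated water endmember systematically pulls
    fractional covers down).
    """
    eligible = scene.ocean_mask & (distance.distance > offshore_min_m)
    if exclude_mask is not None:
        eligible &= ~exclude_mask.astype(bool)
    nir = scene.band("nir")
    if eligible.any():
        cutoff = np.percentile(nir[eligible], glint_percentile)
        eligible = eligible & (nir <= cutoff)
    n_eligible = int(eligible.sum())
    if n_eligible < n:
        raise ValueError(
            f"only {n_eligible} eligible offshore water pixels, need {n}"
        )
    rows, cols = np.nonzero(eligible)
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rows), size=n, replace=False)
    return scene.reflectance[:, rows[pick], cols[pick]].T.copy()


# ---------------------------------------------------------------------------
# MESMA


def mesma_unmix(spectrum: np.ndarray, library: EndmemberLibrary
                ) -> tuple[float, float, int]:
    """Unmix one spectrum against every (kelp, water) two-endmember model.

    For each water endmember ``w`` the sum-to-one linear model
    ``spectrum = f*kelp + (1-f)*w`` has the closed-form least-squares solution
    ``f = <s - w, kelp - w> / ||kelp - w||^2`` with ``f`` unconstrained.
    Returns ``(f, rmse, water_index)`` for the model with the lowest
    reconstruction RMSE over the six bands (ties -> lower water index).
    """
    f, rmse, idx = mesma_unmix_many(np.asarray(spectrum, float)[None, :], library)
    return float(f[0]), float(rmse[0]), int(idx[0])


def mesma_unmix_many(spectra: np.ndarray, library: EndmemberLibrary
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`mesma_unmix` over an (N, 6) spectrum array."""
    s = np.atleast_2d(np.asarray(spectra, dtype=float))  # (N, 6)
    k = library.kelp
    W = library.water  # (M, 6)
    diff = k[None, :] - W  # (M, 6)
    norm2 = np.einsum("mb,mb->m", diff, diff)
    if np.any(norm2 < 1e-20):
        bad = int(np.argmin(norm2))
        raise ValueError(
            f"degenerate library: water endmember {bad} equals the kelp endmember"
        )
    # f[n, m] = <s_n - w_m, k - w_m> / ||k - w_m||^2
    sw = s[:, None, :] - W[None, :, :]  # (N, M, 6)
    f = np.einsum("nmb,mb->nm", sw, diff) / norm2[None, :]
    resid = sw - f[:, :, None] * diff[None, :, :]
    rmse = np.sqrt(np.mean(resid**2, axis=2))  # (N, M)
    best = np.argmin(rmse, axis=1)  # argmin takes the first (lowest id) on ties
    n_idx = np.arange(s.shape[0])
    return f[n_idx, best], rmse[n_idx, best], best


# ---------------------------------------------------------------------------
# scene classification


def classify_scene(
    scene: Scene,
    model: DecisionTreeModel,
    library: EndmemberLibrary,
    threshold_fraction: float = DEFAULT_FRACTION_THRESHOLD,
    distance: DistanceField | None = None,
) -> tuple[FractionalCoverageMap, BinaryCanopyMap]:
    """Screen, unmix, and binarize one scene.

    Candidate pixels (decision-tree positives) get MESMA fractions; binary
    presence is ``fraction >= threshold_fraction`` (inclusive at the 13%
    boundary).  Non-candidate ocean pixels are absent (0); land/cloud pixels
    are missing (NaN) in both products.
    """
    candidates = apply_decision_tree(model, scene, distance)
    shape = scene.grid.shape
    fraction = np.full(shape, np.nan)
    fit_rmse = np.full(shape, np.nan)
    rows, cols = np.nonzero(candidates)
    if len(rows):
        spectra = scene.reflectance[:, rows, cols].T
        f, rmse, _ = mesma_unmix_many(spectra, library)
        fraction[rows, cols] = f
        fit_rmse[rows, cols] = rmse
    presence = np.zeros(shape)
    presence[candidates] = (fraction[candidates] >= threshold_fraction).astype(float)
    presence[~scene.ocean_mask] = np.nan
    fcm = FractionalCoverageMap(grid=scene.grid, fraction=fraction,
                                fit_rmse=fit_rmse, candidate_mask=candidates)
    bcm = BinaryCanopyMap(grid=scene.grid, presence=presence, provenance="dtm",
                          acquired_at=scene.acquired_at, sensor=scene.sensor)
    return fcm, bcm
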