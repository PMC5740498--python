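"""Random-forest imputation and refinement of variant-effect maps.

Missing entries of a variant-effect map are predicted from features of
the measured map (intrinsic averages, chemicophysical deltas, supplied
conservation and structure annotations) with a random-forest regressor,
and low-confidence measurements are refined by confidence-weighted
blending with the model prediction, using the 10-fold cross-validation
RMSD as the prediction's standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from sklearn.ensemble import RandomForestRegressor

from . import aa_properties
from .maps import SCORE_MAP_COLUMNS, variant_key
from .scale_join import join_scores
from .seqcore import AA_ALPHABET, STOP

__all__ = [
    "ForestConfig",
    "build_features",
    "ImputationModel",
    "ImputationResults",
    "impute",
    "transform_hypercomplementers",
    "refine",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

ANNOTATION_COLUMNS = [
    "amas", "sift", "provean", "sec_struct", "solvent_acc", "hbond", "saltbridge",
]
SEC_STRUCT_CATEGORIES = ["helix", "strand", "coil"]


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters (R randomForest regression defaults).

    n_tree=500 trees, mtry = floor(n_feat/3) candidate features per
    split, bootstrap sampling with replacement of n_obs rows, terminal
    node size 5, unlimited depth, one permutation round for feature
    importance.
    """

    n_tree: int = 500
    mtry_fraction: float = 1.0 / 3.0
    nodesize: int = 5
    n_perm: int = 1
    seed: int = 0

    def make_regressor(self) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_tree,
            max_features=self.mtry_fraction,
            min_samples_leaf=self.nodesize,
            bootstrap=True,
            max_samples=None,  # sampsize = n_obs
            random_state=self.seed,
            n_jobs=1,
        )


def _weighted_mean(scores: np.ndarray, se: np.ndarray) -> float:
    """Inverse-variance (1/se^2) weighted mean; NaN when empty."""
    if len(scores) == 0:
        return float("nan")
    w = 1.0 / np.asarray(se, dtype=float) ** 2
    return float(np.sum(w * scores) / np.sum(w))


def build_features(
    score_map: pd.DataFrame,
    protein: str,
    clones: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
    include_nonsense: bool = True,
) -> pd.DataFrame:
    """One feature row per possible variant of the protein.

    Parameters
    ----------
    score_map
        measured variants (score-map columns); used for the intrinsic
        features, with inverse-variance (1/se^2) weighting.
    protein
        wild-type amino-acid sequence.
    clones
        optional BarSeq clone table with columns ``clone_id``,
        ``aa_changes`` (semicolon-joined compact variant strings),
        ``s_prime``, ``se`` — enables the multi-mutant-clone features.
    annotations
        optional per-position table: ``position`` plus any of amas,
        sift, provean, sec_struct (helix/strand/coil), solvent_acc,
        interface_burial_* (one column per partner), hbond, saltbridge.

    Intrinsic positional means are computed leave-one-out: the focal
    variant's own measurement never contributes to its feature value.
    Missing values are left as NaN; the model fills them with training
    medians and adds missingness indicator columns.
    """
    measured = score_map.set_index(variant_key(score_map))
    by_pos: dict[int, pd.DataFrame] = dict(tuple(score_map.groupby("position")))

    rows = []
    mutants = AA_ALPHABET + (STOP if include_nonsense else "")
    for pos, wt in enumerate(protein, start=1):
        at_pos = by_pos.get(pos)
        for mut in mutants:
            if mut == wt:
                continue
            key = f"{wt}{pos}{mut}"
            row: dict = {"position": pos, "wt_aa": wt, "mut_aa": mut, "key": key}
            if at_pos is not None:
                others = at_pos[variant_key(at_pos) != key]
                row["pos_mean_weighted"] = _weighted_mean(
                    others["score"].to_numpy(), others["se"].to_numpy()
                )
            else:
                row["pos_mean_weighted"] = float("nan")
            for prop in aa_properties.PROPERTY_NAMES:
                row[f"d_{prop}"] = aa_properties.delta(prop, wt, mut)
            try:
                row["blosum62"] = float(_BLOSUM62[wt, mut])
            except (KeyError, IndexError):
                row["blosum62"] = float("nan")
            rows.append(row)
    feats = pd.DataFrame(rows)

    if clones is not None:
        multi_mean, mult_est = _clone_features(clones, measured)
        feats["multi_clone_mean"] = feats["key"].map(multi_mean)
        feats["multiplicative_estimate"] = feats["key"].map(mult_est)

    if annotations is not None:
        ann = annotations.set_index("position")
        burial_cols = [c for c in ann.columns if c.startswith("interface_burial")]
        for col in ["amas", "sift", "provean", "solvent_acc", "hbond",
                    "saltbridge", *burial_cols]:
            if col in ann.columns:
                feats[col] = feats["position"].map(ann[col]).astype(float)
        if "sec_struct" in ann.columns:
            ss = feats["position"].map(ann["sec_struct"])
            for cat in SEC_STRUCT_CATEGORIES:
                feats[f"sec_{cat}"] = (ss == cat).astype(float)
    return feats


def _clone_features(
    clones: pd.DataFrame, measured: pd.DataFrame
) -> tuple[dict[str, float], dict[str, float]]:
    """Multi-mutant-clone mean and multiplicative single-variant estimate.

    For a double-mutant clone AB and a measured single mutant B, the
    multiplicative model f_AB = f_A * f_B gives f_A = f_AB / f_B.
    """
    per_variant: dict[str, list[tuple[float, float]]] = {}
    mult: dict[str, list[float]] = {}
    for row in clones.itertuples(index=False):
        changes = [s for s in str(row.aa_changes).split(";") if s]
        if len(changes) < 2:
            continue
        for ch in changes:
            per_variant.setdefault(ch, []).append((row.s_prime, row.se))
        if len(changes) == 2:
            for target, other in (changes, reversed(changes)):
                if other in measured.index:
                    f_other = float(measured.loc[other, "score"])
                    if abs(f_other) > 1e-6:
                        mult.setdefault(target, []).append(row.s_prime / f_other)
    multi_mean = {
        k: _weighted_mean(
            np.array([s for s, _ in v]), np.array([se for _, se in v])
        )
        for k, v in per_variant.items()
    }
    mult_est = {k: float(np.mean(v)) for k, v in mult.items()}
    return multi_mean, mult_est


class ImputationModel:
    """Random-forest regression of map scores on variant features.

    Trained on the measured variants of ``score_map``; predicts every
    variant in ``features``.  Accuracy is estimated by 10-fold
    cross-validation with seeded fold assignment, and feature relevance
    by the increase in mean squared error when a feature column is
    permuted.
    """

    N_FOLDS = 10

    def __init__(
        self,
        score_map: pd.DataFrame,
        features: pd.DataFrame,
        config: ForestConfig = ForestConfig(),
        min_training: int = 50,
    ):
        self.score_map = score_map
        self.features = features
        self.config = config
        self.feature_columns = [
            c
            for c in features.columns
            if c not in ("position", "wt_aa", "mut_aa", "key")
        ]
        keys = set(variant_key(score_map))
        self.train_mask = features["key"].isin(keys).to_numpy()
        n_train = int(self.train_mask.sum())
        if n_train < min_training:
            raise ValueError(
                f"only {n_train} measured variants; need >= {min_training} "
                "(imputation collapses on very sparse maps)"
            )

    # -- design matrix -------------------------------------------------

    def _design(self) -> tuple[np.ndarray, list[str]]:
        X = self.features[self.feature_columns].to_numpy(dtype=float)
        names = list(self.feature_columns)
        train = X[self.train_mask]
        medians = np.nanmedian(train, axis=0)
        medians = np.where(np.isfinite(medians), medians, 0.0)
        indicator_cols = []
        for j, name in enumerate(self.feature_columns):
            col = X[:, j]
            if np.isnan(col).any():
                indicator_cols.append(np.isnan(col).astype(float))
                names.append(f"{name}_missing")
                col[np.isnan(col)] = medians[j]
        if indicator_cols:
            X = np.column_stack([X, *indicator_cols])
        return X, names

    def _response(self) -> np.ndarray:
        m = self.score_map.set_index(variant_key(self.score_map))["score"]
        return m.reindex(self.features.loc[self.train_mask, "key"]).to_numpy()

    # -- fitting -------------------------------------------------------

    def fit(self) -> "ImputationResults":
        X, names = self._design()
        y = self._response()
        Xtr = X[self.train_mask]
        rng = np.random.default_rng(self.config.seed)

        # 10-fold CV by seeded shuffle
        n = len(y)
        order = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[order] = np.arange(n) % self.N_FOLDS
        cv_pred = np.empty(n)
        for f in range(self.N_FOLDS):
            hold = folds == f
            reg = self.config.make_regressor()
            reg.fit(Xtr[~hold], y[~hold])
            cv_pred[hold] = reg.predict(Xtr[hold])
        cv_rmsd = float(np.sqrt(np.mean((cv_pred - y) ** 2)))

        final = self.config.make_regressor()
        final.fit(Xtr, y)
        predictions = final.predict(X)

        importances = self._permutation_importance(final, Xtr, y, names, rng)
        return ImputationResults(
            self, predictions, cv_pred, cv_rmsd, importances, names
        )

    def _permutation_importance(
        self,
        forest: RandomForestRegressor,
        X: np.ndarray,
        y: np.ndarray,
        names: list[str],
        rng: np.random.Generator,
    ) -> pd.Series:
        """Percent increase in MSE when one feature column is permuted."""
        base = float(np.mean((forest.predict(X) - y) ** 2))
        out = {}
        for j, name in enumerate(names):
            incs = []
            for _ in range(self.config.n_perm):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                mse = float(np.mean((forest.predict(Xp) - y) ** 2))
                incs.append(100.0 * (mse - base) / base)
            out[name] = float(np.mean(incs))
        return pd.Series(out).sort_values(ascending=False)


def impute(
    score_map: pd.DataFrame,
    features: pd.DataFrame,
    config: ForestConfig = ForestConfig(),
) -> "ImputationResults":
    """Functional wrapper around :class:`ImputationModel`."""
    return ImputationModel(score_map, features, config).fit()


class ImputationResults:
    """Predictions, cross-validation error and feature importances."""

    def __init__(
        self,
        model: ImputationModel,
        predictions: np.ndarray,
        cv_predictions: np.ndarray,
        cv_rmsd: float,
        importances: pd.Series,
        feature_names: list[str],
    ):
        self.model = model
        self.predictions = pd.Series(
            predictions, index=model.features["key"].to_numpy(), name="prediction"
        )
        self.cv_predictions = cv_predictions
        self.cv_rmsd = cv_rmsd
        self.importances = importances
        self.feature_names = feature_names

    def refine(self, df_virtual: float = 1.0) -> pd.DataFrame:
        """Blend measured scores with predictions; impute missing ones."""
        return refine(self.model.score_map, self, df_virtual=df_virtual)

    def summary(self) -> str:
        top = self.importances.head(5)
        lines = [
            "Random-forest imputation results",
            "=" * 38,
            f"training variants     {int(self.model.train_mask.sum()):>8d}",
            f"predicted variants    {len(self.predictions):>8d}",
            f"10-fold CV RMSD       {self.cv_rmsd:>8.4f}",
            "top features (% increase in MSE):",
        ]
        lines += [f"  {name:<24s}{val:>8.1f}" for name, val in top.items()]
        return "\n".join(lines)


def transform_hypercomplementers(score_map: pd.DataFrame) -> pd.DataFrame:
    """Fold above-wild-type scores back below 1 via the reciprocal rule.

    Above-wild-type growth in the yeast assay is best modelled as
    deleterious in the human context: s -> 1/s for s > 1 (s <= 1
    unchanged).  The sd propagates with the first-order factor 1/s^2.
    The transform is idempotent and maps (0, inf) into (0, 1].
    """
    out = score_map.copy()
    s = out["score"].to_numpy(dtype=float)
    hyper = s > 1.0
    factor = np.where(hyper, 1.0 / s**2, 1.0)
    out["score"] = np.where(hyper, 1.0 / s, s)
    for col in ("sd", "se"):
        if col in out.columns:
            out[col] = out[col].to_numpy(dtype=float) * factor
    return out


def refine(
    score_map: pd.DataFrame,
    result: ImputationResults,
    df_virtual: float = 1.0,
) -> pd.DataFrame:
    """Confidence-weighted blend of measurements and model predictions.

    Each measured variant is joined with its prediction, whose standard
    deviation and error are both taken as the cross-validation RMSD and
    whose degrees of freedom are ``df_virtual``.  Variants absent from
    the measured map are reported as pure predictions with provenance
    "imputed".
    """
    rmsd = result.cv_rmsd
    measured = score_map.set_index(variant_key(score_map))
    feats = result.model.features
    gene = score_map["gene"].iloc[0] if len(score_map) else "GENE"

    rows = []
    for key, pred in result.predictions.items():
        fr = feats.loc[feats.key == key].iloc[0]
        if key in measured.index:
            m = measured.loc[key]
            j = join_scores(
                m["score"], m["sd"], m["se"], m["df"],
                pred, rmsd, rmsd, df_virtual,
            )
            rows.append(
                {
                    "gene": m["gene"], "position": int(m["position"]),
                    "wt_aa": m["wt_aa"], "mut_aa": m["mut_aa"],
                    "score": j.mu_joint, "sd": j.sigma_joint,
                    "se": j.se_joint, "df": j.df_joint,
                    "provenance": "refined",
                }
            )
        else:
            rows.append(
                {
                    "gene": gene, "position": int(fr["position"]),
                    "wt_aa": fr["wt_aa"], "mut_aa": fr["mut_aa"],
                    "score": float(pred), "sd": rmsd, "se": rmsd,
                    "df": df_virtual, "provenance": "imputed",
                }
            )
    return (
        pd.DataFrame(rows, columns=SCORE_MAP_COLUMNS)
        .sort_values(["position", "mut_aa"])
        .reset_index(drop=True)
    )
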