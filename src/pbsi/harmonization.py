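"""Parametric empirical-Bayes batch harmonisation (ComBat).

Location/scale adjustment of feature matrices across acquisition sites,
protecting diagnostic-group effects via covariates in the standardisation
design.  Follows the classic parametric formulation: per-feature
standardisation, batch effect estimation, moment-matched normal /
inverse-gamma priors, and iterative conditional posterior updates.

Each measure class is harmonised in its own fit — measure classes have
different units and pooling them would distort the EB priors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import HarmonizationError
from .io import MorphometryTable

#: Convergence tolerance and iteration cap for the EB conditional updates.
EB_CONVERGENCE = 1e-4
EB_MAX_ITER = 100


@dataclass
class HarmonizationModel:
    """Fitted ComBat parameters for one measure class.

    ``identity=True`` marks a degenerate single-batch fit that applies no
    adjustment.
    """

    measure_class: str
    feature_labels: list[str]
    batch_labels: list[str]
    covariate_labels: list[str]
    grand_mean: np.ndarray          # (features,)
    beta: np.ndarray                # (covariates, features)
    var_pooled: np.ndarray          # (features,)
    gamma_star: np.ndarray          # (batches, features) EB location
    delta2_star: np.ndarray         # (batches, features) EB scale (variance)
    identity: bool = False

    def to_json(self, path: str | Path) -> None:
        """Serialise to a JSON sidecar for audit."""
        payload = {
            "measure_class": self.measure_class,
            "feature_labels": self.feature_labels,
            "batch_labels": self.batch_labels,
            "covariate_labels": self.covariate_labels,
            "grand_mean": self.grand_mean.tolist(),
            "beta": self.beta.tolist(),
            "var_pooled": self.var_pooled.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta2_star": self.delta2_star.tolist(),
            "identity": self.identity,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "HarmonizationModel":
        payload = json.loads(Path(path).read_text())
        for key in ("grand_mean", "beta", "var_pooled", "gamma_star", "delta2_star"):
            payload[key] = np.asarray(payload[key], dtype=float)
        return cls(**payload)


def _group_design(meta: pd.DataFrame, control_group: str) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded group indicators with the control group as reference."""
    groups = meta["group"].astype(str)
    # sorted levels: the design is invariant to subject row order
    levels = sorted(set(groups) - {control_group})
    design = np.column_stack([(groups == g).to_numpy(float) for g in levels]) \
        if levels else np.empty((len(meta), 0))
    return design, [f"group[{g}]" for g in levels]


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (2 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (m * s2 + m ** 3) / s2


def _eb_fit(z_batch: np.ndarray, gamma_hat: np.ndarray, delta_hat2: np.ndarray,
            gamma_bar: float, tau2: float, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    """Iterative conditional posterior estimates for one batch."""
    n = z_batch.shape[0]
    gamma = gamma_hat.copy()
    delta2 = delta_hat2.copy()
    for _ in range(EB_MAX_ITER):
        gamma_new = (n * tau2 * gamma_hat + delta2 * gamma_bar) / (n * tau2 + delta2)
        ssq = ((z_batch - gamma_new[None, :]) ** 2).sum(axis=0)
        delta2_new = (0.5 * ssq + b) / (n / 2.0 + a - 1.0)
        change = max(np.abs(gamma_new - gamma).max(), np.abs(delta2_new - delta2).max())
        gamma, delta2 = gamma_new, delta2_new
        if change < EB_CONVERGENCE:
            break
    return gamma, delta2


def fit_combat(table: MorphometryTable, batch: pd.Series | None = None,
               control_group: str = "HC") -> HarmonizationModel:
    """Fit the EB location/scale model on one measure class.

    ``batch`` defaults to the table's ``site`` column.  Group status is the
    sole protected covariate, treatment-coded against ``control_group``.
    """
    if batch is None:
        batch = table.meta["site"]
    batch = batch.astype(str).loc[table.subject_ids]
    features = list(table.values.columns)
    x = table.values.to_numpy(dtype=float).T            # features x subjects
    n_features, n_subjects = x.shape

    batches = list(pd.unique(batch))
    counts = batch.value_counts()
    if (counts < 2).any():
        tiny = counts[counts < 2].index.tolist()
        raise HarmonizationError(f"batches with a single subject: {tiny}")

    cov, cov_labels = _group_design(table.meta, control_group)

    if len(batches) < 2:
        warnings.warn("single batch: harmonisation is the identity adjustment",
                      stacklevel=2)
        k = cov.shape[1]
        return HarmonizationModel(
            table.measure_class, features, batches, cov_labels,
            grand_mean=np.zeros(n_features), beta=np.zeros((k, n_features)),
            var_pooled=np.ones(n_features),
            gamma_star=np.zeros((1, n_features)),
            delta2_star=np.ones((1, n_features)),
            identity=True,
        )

    onehot = np.column_stack([(batch == b).to_numpy(float) for b in batches])
    design = np.hstack([onehot, cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise HarmonizationError("rank-deficient design (batch + group indicators)")

    b_hat, *_ = np.linalg.lstsq(design, x.T, rcond=None)   # (cols, features)
    n_batches = len(batches)
    batch_sizes = onehot.sum(axis=0)
    grand_mean = (batch_sizes / n_subjects) @ b_hat[:n_batches]
    beta = b_hat[n_batches:]

    fitted = (design @ b_hat).T
    var_pooled = ((x - fitted) ** 2).mean(axis=1)
    if (var_pooled <= 0).any():
        raise HarmonizationError("zero residual variance for some feature")

    cov_part = (cov @ beta).T if beta.size else np.zeros_like(x)
    stand_mean = grand_mean[:, None] + cov_part
    z = (x - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_star = np.empty((n_batches, n_features))
    delta2_star = np.empty((n_batches, n_features))
    for j, b in enumerate(batches):
        idx = (batch == b).to_numpy()
        zb = z[:, idx].T                                    # subjects x features
        gamma_hat = zb.mean(axis=0)
        delta_hat2 = zb.var(axis=0, ddof=1)
        gamma_bar = float(gamma_hat.mean())
        tau2 = float(gamma_hat.var(ddof=1))
        a = _aprior(delta_hat2)
        b_pr = _bprior(delta_hat2)
        gamma_star[j], delta2_star[j] = _eb_fit(
            zb, gamma_hat, delta_hat2, gamma_bar, tau2, a, b_pr
        )
    if (delta2_star <= 0).any():
        raise HarmonizationError("non-positive EB scale estimate")

    return HarmonizationModel(
        table.measure_class, features, batches, cov_labels,
        grand_mean=grand_mean, beta=beta, var_pooled=var_pooled,
        gamma_star=gamma_star, delta2_star=delta2_star,
    )


def apply_combat(model: HarmonizationModel, table: MorphometryTable,
                 batch: pd.Series | None = None,
                 control_group: str = "HC") -> MorphometryTable:
    """Apply a fitted model; metadata is untouched.

    Raises on a batch label absent from the model — there is no
    out-of-sample batch imputation.
    """
    if list(table.values.columns) != model.feature_labels:
        raise HarmonizationError("table features do not match the fitted model")
    out_values = table.values.copy()
    if model.identity:
        return MorphometryTable(table.measure_class, out_values, table.meta.copy())

    if batch is None:
        batch = table.meta["site"]
    batch = batch.astype(str).loc[table.subject_ids]
    unseen = set(batch.unique()) - set(model.batch_labels)
    if unseen:
        raise HarmonizationError(f"unseen batch labels: {sorted(unseen)}")

    cov, cov_labels = _group_design(table.meta, control_group)
    if cov_labels != model.covariate_labels:
        raise HarmonizationError(
            f"covariate design {cov_labels} does not match model {model.covariate_labels}"
        )

    x = out_values.to_numpy(dtype=float).T
    cov_part = (cov @ model.beta).T if model.beta.size else np.zeros_like(x)
    stand_mean = model.grand_mean[:, None] + cov_part
    z = (x - stand_mean) / np.sqrt(model.var_pooled)[:, None]

    batch_idx = batch.map({b: j for j, b in enumerate(model.batch_labels)}).to_numpy()
    gamma = model.gamma_star[batch_idx].T                   # features x subjects
    delta = np.sqrt(model.delta2_star[batch_idx]).T
    adjusted = (z - gamma) / delta * np.sqrt(model.var_pooled)[:, None] + stand_mean

    out_values.loc[:, :] = adjusted.T
    return MorphometryTable(table.measure_class, out_values, table.meta.copy())


def harmonize_tables(tables: dict[str, MorphometryTable],
                     control_group: str = "HC") -> tuple[dict[str, MorphometryTable],
                                                         dict[str, HarmonizationModel]]:
    """Fit and apply ComBat independently per measure class."""
    out: dict[str, MorphometryTable] = {}
    models: dict[str, HarmonizationModel] = {}
    for measure, table in tables.items():
        model = fit_combat(table, control_group=control_group)
        out[measure] = apply_combat(model, table, control_group=control_group)
        models[measure] = model
    return out, models
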