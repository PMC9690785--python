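"""Domain types and I/O for clustered, right-censored, multi-treatment survival data.

The central container is :class:`SurvivalDataset`, a validated rectangular table of
observed follow-up times ``T``, event indicators ``delta`` (1 = event, 0 = right
censored), treatment codes in ``{1..Z}``, cluster identifiers, and pre-treatment
covariates.  Categorical covariates are expanded to indicator columns at load time
(reference level dropped) and the encoding is recorded so downstream reports can
refer to the original levels.

Posterior draws from the riAFT-BART sampler are stored in :class:`PosteriorDraws`
and round-tripped through a single-file, versioned ``.npz`` container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DRAWS_FORMAT_VERSION = 1


class SchemaError(ValueError):
    """A declared column is missing or the schema mapping is incomplete."""


class ValidationError(ValueError):
    """Row-level invariant violation (nonpositive time, bad event code, ...)."""


class FormatError(ValueError):
    """A posterior-draw file is truncated, corrupted, or of an unknown version."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One observation: follow-up time, event status, treatment, cluster, covariates."""

    time: float
    event: int
    treatment: int
    cluster: str
    covariates: np.ndarray

    def validate(self, n_treatments: int, n_covariates: int) -> None:
        if not (self.time > 0 and np.isfinite(self.time)):
            raise ValidationError(f"time must be positive and finite, got {self.time}")
        if self.event not in (0, 1):
            raise ValidationError(f"event must be 0 or 1, got {self.event}")
        if not (1 <= self.treatment <= n_treatments):
            raise ValidationError(
                f"treatment {self.treatment} outside declared range 1..{n_treatments}"
            )
        if len(self.covariates) != n_covariates:
            raise ValidationError("covariate vector length differs across records")


class SurvivalDataset:
    """Validated clustered survival table.

    Parameters
    ----------
    time, event, treatment : arrays of length n
        Follow-up time (>0), event indicator in {0,1}, treatment code in {1..Z}.
    cluster : sequence of identifiers (kept as strings)
        Opaque cluster labels; mapped internally to contiguous indices 0..K-1.
    covariates : (n, p) float array
        Pre-treatment covariates, categoricals already encoded as indicators.
    covariate_names : list of p labels
    n_treatments : int, optional
        Declared Z; defaults to ``max(treatment)``.
    encoding : mapping, optional
        Record of how categorical columns were expanded (column -> dropped
        reference level and retained levels).
    """

    def __init__(
        self,
        time: np.ndarray,
        event: np.ndarray,
        treatment: np.ndarray,
        cluster: Sequence,
        covariates: np.ndarray,
        covariate_names: Sequence[str],
        n_treatments: int | None = None,
        encoding: Mapping | None = None,
        require_all_treatments: bool = True,
    ):
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        self.treatment = np.asarray(treatment, dtype=int)
        self.cluster_labels = np.asarray([str(c) for c in cluster], dtype=object)
        self.covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        self.covariate_names = list(covariate_names)
        self.encoding = dict(encoding or {})

        n = len(self.time)
        if not (
            len(self.event) == len(self.treatment) == len(self.cluster_labels) == n
            and self.covariates.shape[0] == n
        ):
            raise ValidationError("all columns must have equal length")
        if self.covariates.shape[1] != len(self.covariate_names):
            raise ValidationError("covariate_names must match covariate matrix width")

        self.n_treatments = int(n_treatments or self.treatment.max(initial=0))
        self._validate(require_all_treatments)

        # contiguous cluster index, stable in first-appearance order
        uniq = list(dict.fromkeys(self.cluster_labels))
        self.cluster_index = {lab: k for k, lab in enumerate(uniq)}
        self.cluster_codes = np.asarray(
            [self.cluster_index[lab] for lab in self.cluster_labels], dtype=int
        )

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_index)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def record(self, i: int) -> SurvivalRecord:
        return SurvivalRecord(
            time=float(self.time[i]),
            event=int(self.event[i]),
            treatment=int(self.treatment[i]),
            cluster=str(self.cluster_labels[i]),
            covariates=self.covariates[i],
        )

    def _validate(self, require_all_treatments: bool = True) -> None:
        bad = np.flatnonzero(~((self.time > 0) & np.isfinite(self.time)))
        if bad.size:
            raise ValidationError(f"nonpositive or nonfinite time in rows {bad.tolist()}")
        bad = np.flatnonzero(~np.isin(self.event, (0, 1)))
        if bad.size:
            raise ValidationError(f"event not in {{0,1}} in rows {bad.tolist()}")
        if self.n_treatments < 2:
            raise ValidationError("need at least 2 treatment levels")
        bad = np.flatnonzero(
            (self.treatment < 1) | (self.treatment > self.n_treatments)
        )
        if bad.size:
            raise ValidationError(
                f"treatment code outside 1..{self.n_treatments} in rows {bad.tolist()}"
            )
        if not np.isfinite(self.covariates).all():
            raise ValidationError("missing or nonfinite covariate values are rejected")
        # model fitting needs every arm observed; prediction-only tables
        # (e.g. a single profile scored under each arm) may opt out
        if require_all_treatments:
            present = np.unique(self.treatment)
            missing = set(range(1, self.n_treatments + 1)) - set(present.tolist())
            if missing:
                raise ValidationError(
                    f"treatment level(s) {sorted(missing)} have no records"
                )

    # -- design matrix -----------------------------------------------------
    def design_matrix(self, treatment: np.ndarray | int | None = None) -> np.ndarray:
        """Covariates with Z-1 appended treatment indicators (levels 2..Z).

        ``treatment=None`` uses each record's observed arm; an integer builds the
        counterfactual design 'everyone assigned arm a'.
        """
        if treatment is None:
            a = self.treatment
        elif np.isscalar(treatment):
            a = np.full(len(self), int(treatment), dtype=int)
        else:
            a = np.asarray(treatment, dtype=int)
        ind = np.zeros((len(self), self.n_treatments - 1))
        for level in range(2, self.n_treatments + 1):
            ind[:, level - 2] = a == level
        return np.column_stack([self.covariates, ind])

    @property
    def design_names(self) -> list[str]:
        return self.covariate_names + [
            f"treatment_{level}" for level in range(2, self.n_treatments + 1)
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=self.covariate_names)
        df.insert(0, "cluster", self.cluster_labels)
        df.insert(0, "treatment", self.treatment)
        df.insert(0, "event", self.event)
        df.insert(0, "time", self.time)
        return df

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_survival_table(
    path,
    schema: Mapping[str, str] | None = None,
    n_treatments: int | None = None,
) -> SurvivalDataset:
    """Read a delimited survival table and validate it into a :class:`SurvivalDataset`.

    ``schema`` maps the roles ``time``, ``event``, ``treatment``, ``cluster`` to
    column names (defaults: those same names).  Every remaining column is treated
    as a covariate; object/string columns are expanded to indicator columns with
    the first level (alphabetical) as reference, and the encoding is recorded.
    """
    schema = dict(schema or {})
    roles = {r: schema.get(r, r) for r in ("time", "event", "treatment", "cluster")}
    df = pd.read_csv(path)
    missing = [c for c in roles.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")

    covariate_cols = [c for c in df.columns if c not in roles.values()]
    cov_frames: list[pd.DataFrame] = []
    encoding: dict[str, dict] = {}
    for c in covariate_cols:
        col = df[c]
        if col.isna().any():
            rows = np.flatnonzero(col.isna().to_numpy()).tolist()
            raise ValidationError(f"missing values in covariate '{c}' rows {rows}")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(map(str, col.astype(str).unique()))
            ref, kept = levels[0], levels[1:]
            enc = pd.DataFrame(
                {f"{c}={lev}": (col.astype(str) == lev).astype(float) for lev in kept}
            )
            encoding[c] = {"reference": ref, "levels": kept}
            cov_frames.append(enc)
        else:
            cov_frames.append(col.astype(float).to_frame())
    cov = (
        pd.concat(cov_frames, axis=1)
        if cov_frames
        else pd.DataFrame(index=df.index)
    )

    return SurvivalDataset(
        time=df[roles["time"]].to_numpy(float),
        event=df[roles["event"]].to_numpy(),
        treatment=df[roles["treatment"]].to_numpy(),
        cluster=df[roles["cluster"]].tolist(),
        covariates=cov.to_numpy(float).reshape(len(df), -1),
        covariate_names=list(cov.columns),
        n_treatments=n_treatments,
        encoding=encoding,
    )


@dataclass
class McmcConfig:
    """Sampler settings and hyperparameters for riAFT-BART.

    ``n_trees`` trees in the ensemble, tree depth prior alpha(1+d)^(-beta),
    leaf prior scale sigma_mu = 0.5 / (leaf_scale_k * sqrt(m)) on the internally
    scaled outcome, scaled-inverse-chi-square prior on the error variance
    calibrated at quantile ``sigma_prior_q`` with ``sigma_prior_nu`` df, and an
    inverse-gamma(tau_prior_a, tau_prior_b) prior on the cluster variance.
    """

    n_trees: int = 200
    n_burn: int = 1000
    n_keep: int = 1000
    thin: int = 1
    tree_prior_alpha: float = 0.95
    tree_prior_beta: float = 2.0
    leaf_scale_k: float = 2.0
    sigma_prior_nu: float = 3.0
    sigma_prior_q: float = 0.90
    tau_prior_a: float = 1.0
    tau_prior_b: float = 0.001
    seed: int = 0
    keep_forests: bool = True

    def validate(self) -> None:
        if min(self.n_trees, self.n_burn + 1, self.n_keep, self.thin) < 1:
            raise ValueError("tree/iteration counts must be positive")
        if not (0 < self.tree_prior_alpha < 1):
            raise ValueError("tree_prior_alpha must lie in (0,1)")
        if self.tree_prior_beta < 0:
            raise ValueError("tree_prior_beta must be >= 0")
        for name in ("leaf_scale_k", "sigma_prior_nu", "sigma_prior_q",
                     "tau_prior_a", "tau_prior_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PosteriorDraws:
    """Retained MCMC samples from :func:`riaft_bart.riaft_mcmc.fit_riaft`.

    All stored quantities are on the *log-time* scale of the input data (the
    internal affine scaling has been inverted); the scaling constants used
    during fitting are recorded in ``y_center``/``y_scale``.

    Attributes
    ----------
    train_fit : (n_keep, n) array
        Posterior draws of f(A_i, x_i) for the training records (no intercept).
    intercepts : (n_keep, K) array
        Cluster random intercepts b_j per draw.
    sigma, tau : (n_keep,) arrays
        Residual SD and cluster-intercept SD per draw.
    latent : (n_keep, n) array
        Latent log event times (equal to the observed log time for events).
    forests : list of per-draw compact forests, or None
        Each forest is a dict of flat node arrays enabling prediction at new
        covariate values.
    """

    train_fit: np.ndarray
    intercepts: np.ndarray
    sigma: np.ndarray
    tau: np.ndarray
    latent: np.ndarray
    y_center: float
    y_scale: float
    cluster_ids: list[str]
    design_names: list[str]
    n_treatments: int
    seed: int
    forests: list[dict] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_keep(self) -> int:
        return self.sigma.shape[0]

    def validate(self) -> None:
        if not (self.sigma > 0).all():
            raise ValidationError("sigma must be positive in every draw")
        if not (self.tau >= 0).all():
            raise ValidationError("tau must be nonnegative in every draw")
        if not (
            self.train_fit.shape[0]
            == self.intercepts.shape[0]
            == self.latent.shape[0]
            == self.n_keep
        ):
            raise ValidationError("draw arrays disagree on number of retained draws")

    def cluster_code(self, cluster_id) -> int:
        try:
            return self.cluster_ids.index(str(cluster_id))
        except ValueError:
            raise KeyError(
                f"unknown cluster {cluster_id!r}; pass cluster='new' for a marginal "
                "prediction"
            ) from None


def save_draws(draws: PosteriorDraws, path) -> None:
    """Serialize posterior draws to a single versioned ``.npz`` container."""
    draws.validate()
    payload = {
        "format_version": np.asarray(DRAWS_FORMAT_VERSION),
        "train_fit": draws.train_fit,
        "intercepts": draws.intercepts,
        "sigma": draws.sigma,
        "tau": draws.tau,
        "latent": draws.latent,
        "y_center": np.asarray(draws.y_center),
        "y_scale": np.asarray(draws.y_scale),
        "cluster_ids": np.asarray(draws.cluster_ids, dtype=object),
        "design_names": np.asarray(draws.design_names, dtype=object),
        "n_treatments": np.asarray(draws.n_treatments),
        "seed": np.asarray(draws.seed),
        "meta_json": np.asarray(json.dumps(draws.meta)),
    }
    if draws.forests is not None:
        payload["n_forests"] = np.asarray(len(draws.forests))
        for s, forest in enumerate(draws.forests):
            for key, arr in forest.items():
                payload[f"forest_{s}_{key}"] = arr
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_draws(path) -> PosteriorDraws:
    """Load a posterior-draw container written by :func:`save_draws`."""
    try:
        with np.load(path, allow_pickle=True) as z:
            if "format_version" not in z:
                raise FormatError(f"{path} is not a posterior-draw container")
            version = int(z["format_version"])
            if version != DRAWS_FORMAT_VERSION:
                raise FormatError(
                    f"unsupported draws format version {version} "
                    f"(supported: {DRAWS_FORMAT_VERSION})"
                )
            forests = None
            if "n_forests" in z:
                forests = []
                keys = ("var", "cut", "left", "right", "value", "tree_offsets")
                for s in range(int(z["n_forests"])):
                    forests.append({k: z[f"forest_{s}_{k}"] for k in keys})
            draws = PosteriorDraws(
                train_fit=z["train_fit"],
                intercepts=z["intercepts"],
                sigma=z["sigma"],
                tau=z["tau"],
                latent=z["latent"],
                y_center=float(z["y_center"]),
                y_scale=float(z["y_scale"]),
                cluster_ids=[str(c) for c in z["cluster_ids"]],
                design_names=[str(c) for c in z["design_names"]],
                n_treatments=int(z["n_treatments"]),
                seed=int(z["seed"]),
                forests=forests,
                meta=json.loads(str(z["meta_json"])),
            )
    except FormatError:
        raise
    except Exception as exc:  # zipfile/np errors on truncated or corrupt input
        raise FormatError(f"could not read posterior draws from {path}: {exc}") from exc
    draws.validate()
    return draws
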