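"""The interaction-cost-index regression.

The per-individual cost h_ij of carabid j consuming one seed of taxon i
lumps handling time, innate preference and all other costs into a single
quantity. It is estimated from published cafeteria (choice) experiments:
observed daily consumption x_i is assumed proportional to the risk index
r_i = E_i / h_i, so h_i = E_i / x_i, comparable within but not between
experiments. ln(h) is then regressed on the cube root of seed mass, the
log of carabid mass and their interaction, with the source study as a
random intercept and case weights 1 / M_i^(1/3) to damp the influence of
the few very large seeds:

    ln h_ij = b0 + b1 * M_i^(1/3) + b2 * ln M_j + b3 * M_i^(1/3) ln M_j + study_k

The published fit gives (b0, b1, b2, b3) = (-14.2177, 8.739, 1.720,
-1.278); those are the package defaults, so risk indices can be predicted
for any seed/carabid mass pair without re-fitting.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

logger = logging.getLogger(__name__)

PARAM_NAMES = ("b0", "b1", "b2", "b3")
TERM_LABELS = ("intercept", "seed_mass^(1/3)", "ln(carabid_mass)",
               "seed_mass^(1/3) x ln(carabid_mass)")


class ExtrapolationWarning(UserWarning):
    """Seed mass outside the range of the source feeding trials."""


class FitError(RuntimeError):
    """The cost-model regression could not be estimated."""


@dataclass
class CostModelCoefficients:
    """Fixed effects of the log interaction-cost regression.

    ``study_offsets`` holds additive per-study intercepts (random-effect
    predictions or fixed-effect estimates), used only when predicting on
    the scale of a particular source experiment.
    """

    b0: float = -14.2177
    b1: float = 8.739
    b2: float = 1.720
    b3: float = -1.278
    study_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"coefficient {name} must be finite")

    @property
    def crossover_seed_mass_mg(self) -> float:
        """Seed mass at which d(ln h)/d(ln M_j) = b2 + b3*M_i^(1/3) changes sign.

        Above this mass the interaction cost falls with carabid size;
        below it, it rises. Infinite if b3 = 0.
        """
        if self.b3 == 0:
            return math.inf
        return (-self.b2 / self.b3) ** 3

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d) -> "CostModelCoefficients":
        d = dict(d)
        d.setdefault("study_offsets", {})
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CostModelCoefficients":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CafeteriaRecord:
    """One seed x carabid observation from a choice experiment."""

    study_id: str
    carabid_species: str
    carabid_mass_mg: float
    seed_species: str
    seed_mass_mg: float
    seed_energy_kJ: float
    consumption_per_day: Optional[float] = None
    n_seeds_offered: Optional[float] = None
    ct50_days: Optional[float] = None

    def __post_init__(self) -> None:
        has_x = self.consumption_per_day is not None
        has_ct = self.n_seeds_offered is not None and self.ct50_days is not None
        if has_x == has_ct:
            raise ValueError(
                "provide exactly one of consumption_per_day or "
                "(n_seeds_offered, ct50_days)"
            )
        if not has_x:
            self.consumption_per_day = consumption_from_ct50(
                self.n_seeds_offered, self.ct50_days
            )

    @property
    def log_h(self) -> float:
        return math.log(h_from_consumption(self.seed_energy_kJ, self.consumption_per_day))


def consumption_from_ct50(n_seeds_offered: float, ct50_days: float) -> float:
    """Daily consumption rate x = (0.5 * seeds offered) / CT50.

    CT50 is the time (days) for a beetle to remove half the seeds offered.
    """
    if n_seeds_offered < 1:
        raise ValueError("n_seeds_offered must be >= 1")
    if ct50_days <= 0:
        raise ValueError("ct50_days must be > 0")
    return 0.5 * n_seeds_offered / ct50_days


def h_from_consumption(seed_energy_kJ: float, consumption_per_day: float) -> float:
    """Interaction cost h = E_i / x_i from observed consumption.

    Valid for comparisons within one experiment only: a common rescaling of
    all x or all E in a study shifts every ln(h) by a constant, which the
    study intercept absorbs.
    """
    if seed_energy_kJ <= 0:
        raise ValueError("seed energy must be > 0")
    if consumption_per_day <= 0:
        raise ValueError("consumption rate must be > 0 to derive a cost")
    return seed_energy_kJ / consumption_per_day


def predict_log_h(
    seed_mass_mg,
    carabid_mass_mg,
    coefs: Optional[CostModelCoefficients] = None,
    study: Optional[str] = None,
    extrapolation_threshold_mg: Optional[float] = 8.9,
):
    """Predicted ln(h) for seed/carabid mass pairs (broadcasting).

    ``study`` adds that study's offset (prediction on the source
    experiment's scale). Seed masses above ``extrapolation_threshold_mg``
    emit :class:`ExtrapolationWarning`; pass ``None`` to silence.
    """
    coefs = coefs or CostModelCoefficients()
    mi = np.asarray(seed_mass_mg, dtype=float)
    mj = np.asarray(carabid_mass_mg, dtype=float)
    if np.any(mi <= 0) or np.any(mj <= 0):
        raise ValueError("masses must be > 0")
    if extrapolation_threshold_mg is not None:
        n_over = int(np.count_nonzero(mi > extrapolation_threshold_mg))
        if n_over:
            warnings.warn(
                f"{n_over} seed mass value(s) exceed {extrapolation_threshold_mg} mg, "
                "the largest seed in the feeding trials behind the default fit; "
                "predicted costs are extrapolations",
                ExtrapolationWarning,
                stacklevel=2,
            )
    u = np.cbrt(mi)
    v = np.log(mj)
    out = coefs.b0 + coefs.b1 * u + coefs.b2 * v + coefs.b3 * u * v
    if study is not None:
        out = out + coefs.study_offsets.get(study, 0.0)
    if np.isscalar(seed_mass_mg) and np.isscalar(carabid_mass_mg):
        return float(out)
    return out


def risk_index(seed_energy_kJ, h):
    """Risk index r = E_i / h ("profitability" in optimal foraging terms).

    Density-independent: the no-switching case of frequency-dependent prey
    selection.
    """
    e = np.asarray(seed_energy_kJ, dtype=float)
    hh = np.asarray(h, dtype=float)
    if np.any(e <= 0):
        raise ValueError("seed energy must be > 0")
    if np.any(hh <= 0):
        raise ValueError("interaction cost h must be > 0")
    out = e / hh
    if np.isscalar(seed_energy_kJ) and np.isscalar(h):
        return float(out)
    return out


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "log_h" not in df.columns:
            df["log_h"] = np.log(
                df["seed_energy_kJ"] / df["consumption_per_day"]
            )
        return df
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "seed_mass_mg": r.seed_mass_mg,
                "carabid_mass_mg": r.carabid_mass_mg,
                "log_h": r.log_h,
            }
        )
    return pd.DataFrame(rows)


class InteractionCostModel:
    """Weighted regression of ln(h) on seed and carabid size.

    Parameters
    ----------
    log_h : array-like
        Response, ln of the derived interaction cost.
    seed_mass_mg, carabid_mass_mg : array-like
        Masses entering the design as M_i^(1/3), ln M_j and their product.
    study : array-like of labels, optional
        Source experiment of each record, modelled as an intercept shift.

    Use :meth:`from_records` to build directly from cafeteria data.
    """

    def __init__(self, log_h, seed_mass_mg, carabid_mass_mg, study=None):
        self.y = np.asarray(log_h, dtype=float)
        self.seed_mass = np.asarray(seed_mass_mg, dtype=float)
        self.carabid_mass = np.asarray(carabid_mass_mg, dtype=float)
        n = self.y.size
        if self.seed_mass.size != n or self.carabid_mass.size != n:
            raise ValueError("log_h, seed_mass_mg and carabid_mass_mg must align")
        if np.any(self.seed_mass <= 0) or np.any(self.carabid_mass <= 0):
            raise ValueError("masses must be > 0")
        self.study = (
            np.asarray(study) if study is not None else np.zeros(n, dtype=int)
        )
        self.studies = [str(s) for s in pd.unique(self.study)]
        u = np.cbrt(self.seed_mass)
        v = np.log(self.carabid_mass)
        self.exog = np.column_stack([np.ones(n), u, v, u * v])
        self._check_rank()

    @classmethod
    def from_records(
        cls, records: Iterable[CafeteriaRecord] | pd.DataFrame
    ) -> "InteractionCostModel":
        df = _records_to_frame(records)
        return cls(
            df["log_h"], df["seed_mass_mg"], df["carabid_mass_mg"], df["study_id"]
        )

    def _check_rank(self) -> None:
        if np.unique(self.seed_mass).size < 2:
            raise FitError("design is rank deficient: need >= 2 distinct seed "
                           "masses (seed_mass^(1/3) term is collinear with the intercept)")
        if np.unique(self.carabid_mass).size < 2:
            raise FitError("design is rank deficient: need >= 2 distinct carabid "
                           "masses (ln(carabid_mass) term is collinear with the intercept)")
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            # identify which terms correlate perfectly
            corr = np.corrcoef(self.exog[:, 1:], rowvar=False)
            bad = [
                f"{TERM_LABELS[i + 1]} ~ {TERM_LABELS[j + 1]}"
                for i in range(3)
                for j in range(i + 1, 3)
                if abs(corr[i, j]) > 1 - 1e-10
            ]
            raise FitError(
                "design is rank deficient; collinear terms: " + "; ".join(bad or ["unknown"])
            )

    def _weights(self, weighting: str) -> np.ndarray:
        if weighting == "inverse_cuberoot_mass":
            return self.seed_mass ** (-1.0 / 3.0)
        if weighting == "none":
            return np.ones_like(self.y)
        raise ValueError("weighting must be 'inverse_cuberoot_mass' or 'none'")

    def fit(
        self,
        weighting: str = "inverse_cuberoot_mass",
        study_effect: str = "random",
    ) -> "InteractionCostResults":
        """Estimate the four fixed effects (and study offsets).

        ``study_effect='random'`` fits a random study intercept by profiled
        REML on the weighted marginal likelihood; ``'fixed'`` uses
        sum-to-zero study dummies in weighted least squares; ``'none'``
        pools the studies. With a single study the study effect degrades to
        'none' with a logged warning.
        """
        w = self._weights(weighting)
        n_studies = len(self.studies)
        if study_effect not in ("random", "fixed", "none"):
            raise ValueError("study_effect must be 'random', 'fixed' or 'none'")
        effective = study_effect
        if study_effect != "none" and n_studies < 2:
            logger.warning(
                "only one study present; fitting without a study effect"
            )
            effective = "none"
        if effective == "random":
            return self._fit_random(w, weighting, study_effect)
        return self._fit_wls(w, weighting, study_effect, fixed=(effective == "fixed"))

    # -- weighted least squares (no or fixed study effect) ----------------

    def _fit_wls(self, w, weighting, requested, fixed: bool):
        import statsmodels.api as sm

        X = self.exog
        offsets: dict[str, float] = {}
        if fixed:
            # sum-to-zero coding: K-1 columns, last study = -sum(others)
            labels = self.studies
            Z = np.zeros((self.y.size, len(labels) - 1))
            for k, lab in enumerate(labels[:-1]):
                Z[:, k] = (self.study.astype(str) == lab).astype(float)
            Z[self.study.astype(str) == labels[-1], :] = -1.0
            X = np.column_stack([X, Z])
        res = sm.WLS(self.y, X, weights=w).fit()
        params = res.params[:4]
        bse = res.bse[:4]
        if fixed:
            est = res.params[4:]
            offsets = dict(zip(self.studies[:-1], est))
            offsets[self.studies[-1]] = -float(np.sum(est))
        coefs = CostModelCoefficients(
            *(float(p) for p in params),
            study_offsets={k: float(v) for k, v in offsets.items()},
        )
        return InteractionCostResults(
            model=self,
            coefficients=coefs,
            bse=np.asarray(bse, dtype=float),
            sigma2=float(res.scale),
            tau2=0.0,
            weighting=weighting,
            study_effect_requested=requested,
            study_effect_used="fixed" if fixed else "none",
            df_resid=int(res.df_resid),
        )

    # -- profiled REML with a random study intercept -----------------------

    def _fit_random(self, w, weighting, requested):
        y, X = self.y, self.exog
        n, p = X.shape
        groups = [np.flatnonzero(self.study.astype(str) == s) for s in self.studies]

        def solve(lam):
            """GLS at variance ratio lam = tau^2/sigma^2.

            V = diag(1/w) + lam * J per study block; the inverse uses
            Woodbury: V^-1 = W - lam (W1)(W1)'/(1 + lam * sum(w)).
            """
            XtVX = np.zeros((p, p))
            XtVy = np.zeros(p)
            ytVy = 0.0
            logdet = 0.0
            parts = []
            for idx in groups:
                wk = w[idx]
                Xk, yk = X[idx], y[idx]
                sk = wk.sum()
                shrink = lam / (1.0 + lam * sk)
                wX = wk[:, None] * Xk
                wy = wk * yk
                a = wX.sum(axis=0)  # X' W 1
                b = wy.sum()        # y' W 1
                XtVX += Xk.T @ wX - shrink * np.outer(a, a)
                XtVy += Xk.T @ wy - shrink * a * b
                ytVy += yk @ wy - shrink * b * b
                logdet += -np.log(wk).sum() + np.log1p(lam * sk)
                parts.append((idx, wk, shrink, sk))
            beta = np.linalg.solve(XtVX, XtVy)
            rss = ytVy - XtVy @ beta  # r' V^-1 r at the GLS solution
            return beta, XtVX, rss, logdet, parts

        def reml(log_lam):
            lam = np.exp(log_lam)
            _, XtVX, rss, logdet, _ = solve(lam)
            sign, logdet_xvx = np.linalg.slogdet(XtVX)
            if sign <= 0 or rss <= 0:
                return np.inf
            return logdet + logdet_xvx + (n - p) * np.log(rss)

        opt = optimize.minimize_scalar(reml, bounds=(-12.0, 12.0), method="bounded")
        if not opt.success or not np.isfinite(opt.fun):
            logger.warning("random-intercept REML did not converge; "
                           "falling back to fixed study intercepts")
            return self._fit_wls(w, weighting, requested, fixed=True)
        lam = float(np.exp(opt.x))
        beta, XtVX, rss, _, parts = solve(lam)
        sigma2 = rss / (n - p)
        tau2 = lam * sigma2
        cov = sigma2 * np.linalg.inv(XtVX)
        bse = np.sqrt(np.diag(cov))
        # BLUPs: a_k = lam * 1' V_k^-1 r_k (in sigma^2 units)
        resid = y - X @ beta
        offsets = {}
        for s, (idx, wk, shrink, sk) in zip(self.studies, parts):
            rk = resid[idx]
            wr = wk * rk
            one_vinv_r = wr.sum() - shrink * sk * wr.sum()
            offsets[s] = float(lam * one_vinv_r)
        coefs = CostModelCoefficients(*(float(b) for b in beta), study_offsets=offsets)
        return InteractionCostResults(
            model=self,
            coefficients=coefs,
            bse=bse,
            sigma2=float(sigma2),
            tau2=float(tau2),
            weighting=weighting,
            study_effect_requested=requested,
            study_effect_used="random",
            df_resid=n - p,
        )


@dataclass
class InteractionCostResults:
    """Fit results: estimates, uncertainties and diagnostics."""

    model: InteractionCostModel
    coefficients: CostModelCoefficients
    bse: np.ndarray
    sigma2: float
    tau2: float
    weighting: str
    study_effect_requested: str
    study_effect_used: str
    df_resid: int

    @property
    def params(self) -> np.ndarray:
        c = self.coefficients
        return np.array([c.b0, c.b1, c.b2, c.b3])

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """(4, 2) array of t-based confidence bounds for b0..b3."""
        tval = stats.t.ppf(1 - alpha / 2, self.df_resid)
        p = self.params
        return np.column_stack([p - tval * self.bse, p + tval * self.bse])

    def predict(self, seed_mass_mg, carabid_mass_mg, study=None, **kw):
        return predict_log_h(seed_mass_mg, carabid_mass_mg, self.coefficients,
                             study=study, **kw)

    @property
    def fittedvalues(self) -> np.ndarray:
        m = self.model
        out = m.exog @ self.params
        off = self.coefficients.study_offsets
        if off:
            out = out + np.array([off.get(str(s), 0.0) for s in m.study])
        return out

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Interaction cost model: ln(h) ~ seed_mass^(1/3) * ln(carabid_mass)",
            f"n = {self.model.y.size}, studies = {len(self.model.studies)}, "
            f"weighting = {self.weighting}, study effect = {self.study_effect_used}",
            f"sigma^2 = {self.sigma2:.4g}, tau^2 (study) = {self.tau2:.4g}",
            f"{'term':<36}{'coef':>12}{'se':>10}{'[0.025':>12}{'0.975]':>10}",
        ]
        for name, est, se, (lo, hi) in zip(TERM_LABELS, self.params, self.bse, ci):
            lines.append(f"{name:<36}{est:>12.4f}{se:>10.4f}{lo:>12.4f}{hi:>10.4f}")
        if self.coefficients.study_offsets:
            offs = ", ".join(
                f"{k}: {v:+.4f}" for k, v in self.coefficients.study_offsets.items()
            )
            lines.append(f"study offsets: {offs}")
        return "\n".join(lines)


def fit_cost_model(
    records: Iterable[CafeteriaRecord] | pd.DataFrame,
    weighting: str = "inverse_cuberoot_mass",
    study_effect: str = "random",
) -> InteractionCostResults:
    """Fit the interaction-cost regression to cafeteria records.

    Convenience wrapper around
    ``InteractionCostModel.from_records(records).fit(...)``.
    """
    return InteractionCostModel.from_records(records).fit(
        weighting=weighting, study_effect=study_effect
    )
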