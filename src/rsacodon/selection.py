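"""Model-space enumeration, AIC ranking, likelihood-ratio tests, grouped fits.

Each of the three GY94 parameters (omega, t, kappa) can be constant, linear
in RSA, or per-bin, giving 3^3 = 27 model variants. Models are ranked by
AIC = 2 df − 2 lnL; nested pairs are compared by likelihood-ratio test
against the asymptotic chi-square. Grouped fits share the kappa and t forms
across groups of genes (e.g. large-core vs small-core, high- vs
low-expression) while fitting group-specific omega–RSA lines, with optional
ties on the intercepts and/or slopes for hypothesis tests.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .likelihood import (
    PARAM_BOUNDS,
    START_VALUES,
    BinnedPairData,
    FitResult,
    OptimizerConfig,
    _bin_log_likelihood,
    _LOG_FLOOR,
)
from .model import FORM_DF, FORMS, ModelSpec, ParamForm, validate_frequencies

_FORM_ORDER = {"constant": 0, "linear": 1, "per_bin": 2}


def count_df(spec: ModelSpec, n_bins: int | None = None) -> int:
    """Free-parameter count: constant 1, linear 2, per-bin n_bins per parameter.

    Codon frequencies are fixed during optimization and not counted.
    """
    if n_bins is not None and n_bins != spec.n_bins:
        spec = ModelSpec(family=spec.family, forms=spec.forms, n_bins=n_bins)
    return spec.n_free_params()


def aic(lnL: float, df: int) -> float:
    """Akaike Information Criterion, 2 df − 2 lnL (lower is better)."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return 2.0 * df - 2.0 * lnL


def enumerate_specs(family: str = "GY94", n_bins: int = 20) -> list[ModelSpec]:
    """All 27 parameterization variants of the family (3 forms x 3 parameters)."""
    from .model import FAMILY_PARAMS

    names = FAMILY_PARAMS[family.upper()]
    return [
        ModelSpec.make(family, n_bins=n_bins, **dict(zip(names, combo)))
        for combo in itertools.product(FORMS, repeat=len(names))
    ]


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def _slope_sign(form: ParamForm, midpoints: np.ndarray, tol: float = 1e-4) -> str:
    """'+', '−', or '0': RSA trend of a fitted parameter.

    Constants are flagged '0'; linear forms use the fitted slope; per-bin
    forms use the least-squares slope of the bin values against mid-points.
    """
    if form.form == "constant":
        return "0"
    if form.form == "linear":
        slope = form.values[1]
    else:
        vals = np.asarray(form.values, dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() < 2:
            return "0"
        slope = np.polyfit(midpoints[ok], vals[ok], 1)[0]
    if slope > tol:
        return "+"
    if slope < -tol:
        return "−"
    return "0"


@dataclass
class ModelRanking:
    """Fits sorted by ascending AIC with ΔAIC relative to the best."""

    results: list[FitResult]
    delta_aic: np.ndarray

    @property
    def best(self) -> FitResult:
        return self.results[0]

    def to_dataframe(self, midpoints: np.ndarray | None = None) -> pd.DataFrame:
        rows = []
        for fit, d in zip(self.results, self.delta_aic):
            row = {name: form for name, form in fit.spec.forms}
            row.update(
                lnL=fit.lnL,
                df=fit.df,
                AIC=int(round(fit.aic)),
                delta_AIC=float(d),
            )
            if midpoints is not None:
                for name in ("t", "kappa", "alpha", "beta"):
                    if name in fit.estimates:
                        row[f"{name}_slope_sign"] = _slope_sign(
                            fit.estimates[name], midpoints
                        )
            rows.append(row)
        return pd.DataFrame(rows)


def rank_models(fits: Sequence[FitResult]) -> ModelRanking:
    """Sort fits by ascending AIC; ties broken by smaller df, then model name."""
    if not fits:
        raise ValueError("need at least one fit to rank")
    ordered = sorted(fits, key=lambda f: (f.aic, f.df, f.spec.name))
    delta = np.array([f.aic - ordered[0].aic for f in ordered])
    return ModelRanking(results=list(ordered), delta_aic=delta)


# ---------------------------------------------------------------------------
# Likelihood-ratio tests
# ---------------------------------------------------------------------------

def is_nested(nested: ModelSpec, full: ModelSpec) -> bool:
    """True if ``nested`` is a restriction of ``full``.

    Forms are ordered constant ⊂ linear ⊂ per-bin for each parameter (a
    constant is a zero-slope line; a line is representable per bin).
    """
    if nested.family != full.family or nested.n_bins != full.n_bins:
        return False
    return all(
        _FORM_ORDER[nested.form_of(name)] <= _FORM_ORDER[full.form_of(name)]
        for name in nested.param_names
    )


def lrt(nested: FitResult, full: FitResult, tol: float = 1e-3):
    """Likelihood-ratio test of a nested model against a fuller one.

    Returns (statistic, df_diff, p) with statistic = 2(lnL_full − lnL_nested)
    and p from the chi-square with df_diff degrees of freedom. Small negative
    statistics within optimizer tolerance are clamped to zero.
    """
    spec_n = getattr(nested, "spec", None)
    spec_f = getattr(full, "spec", None)
    if isinstance(spec_n, ModelSpec) and isinstance(spec_f, ModelSpec):
        if not is_nested(spec_n, spec_f):
            raise ValueError(
                f"{spec_n.name} is not nested within {spec_f.name}"
            )
    df_diff = full.df - nested.df
    if df_diff < 1:
        raise ValueError(f"full model must have more df than nested (diff={df_diff})")
    stat = 2.0 * (full.lnL - nested.lnL)
    if stat < -tol:
        raise ValueError(
            f"nested lnL {nested.lnL} exceeds full lnL {full.lnL}: refit the full model"
        )
    stat = max(stat, 0.0)
    p = float(scipy.stats.chi2.sf(stat, df_diff))
    return stat, df_diff, p


# ---------------------------------------------------------------------------
# Grouped fits with parameter tying
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupedSpec:
    """Joint model over gene groups: shared kappa/t, group-wise omega lines.

    omega is linear in RSA within every group, omega_g(r) = omega0[g] +
    omega1[g] r. ``intercept_ties`` / ``slope_ties`` map each group label to
    a tie label; groups with the same tie label share that coefficient.
    Identity maps give fully group-specific lines; mapping every group to
    one label ties the coefficient across all groups.
    """

    groups: tuple[str, ...]
    t_form: str = "linear"
    kappa_form: str = "linear"
    intercept_ties: tuple[tuple[str, str], ...] = ()
    slope_ties: tuple[tuple[str, str], ...] = ()
    n_bins: int = 20

    @staticmethod
    def make(
        groups: Sequence[str],
        t_form: str = "linear",
        kappa_form: str = "linear",
        intercept_ties: Mapping[str, str] | None = None,
        slope_ties: Mapping[str, str] | None = None,
        n_bins: int = 20,
    ) -> "GroupedSpec":
        groups = tuple(groups)
        if len(groups) < 2:
            raise ValueError("grouped fits need at least 2 groups")
        for f in (t_form, kappa_form):
            if f not in FORMS:
                raise ValueError(f"unknown parameter form {f!r}")
        iti = dict(intercept_ties) if intercept_ties else {g: g for g in groups}
        sti = dict(slope_ties) if slope_ties else {g: g for g in groups}
        for ties in (iti, sti):
            if set(ties) != set(groups):
                raise ValueError("tie map must cover exactly the group labels")
        return GroupedSpec(
            groups=groups,
            t_form=t_form,
            kappa_form=kappa_form,
            intercept_ties=tuple(sorted(iti.items())),
            slope_ties=tuple(sorted(sti.items())),
            n_bins=n_bins,
        )

    @property
    def intercept_map(self) -> dict[str, str]:
        return dict(self.intercept_ties)

    @property
    def slope_map(self) -> dict[str, str]:
        return dict(self.slope_ties)

    def n_free_params(self) -> int:
        """Joint df: shared t and kappa df plus one per unique tie label."""
        shared = sum(FORM_DF.get(f, self.n_bins) for f in (self.t_form, self.kappa_form))
        return (
            shared
            + len(set(self.intercept_map.values()))
            + len(set(self.slope_map.values()))
        )


@dataclass
class GroupedFitResult:
    """Joint ML fit across groups with tied/free omega-line coefficients."""

    spec: GroupedSpec
    omega_lines: dict[str, tuple[float, float]]
    t_estimate: ParamForm
    kappa_estimate: ParamForm
    lnL: float
    df: int
    aic: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "groups": list(self.spec.groups),
            "t_form": self.spec.t_form,
            "kappa_form": self.spec.kappa_form,
            "omega_lines": {
                g: {"intercept": a, "slope": b}
                for g, (a, b) in self.omega_lines.items()
            },
            "t": list(self.t_estimate.values),
            "kappa": list(self.kappa_estimate.values),
            "lnL": self.lnL,
            "df": self.df,
            "AIC": self.aic,
            "converged": self.converged,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


class _SharedPacking:
    """Free vector layout for a shared (t or kappa) parameter over the union
    of occupied bins, using the endpoint transform for linear forms."""

    def __init__(self, name: str, form: str, occ: np.ndarray, mids: np.ndarray):
        self.name, self.form, self.occ = name, form, occ
        self.mids_occ = mids[occ - 1]
        self.r_lo = float(self.mids_occ.min())
        self.r_hi = float(self.mids_occ.max())
        if form == "constant":
            self.k = 1
        elif form == "linear":
            if self.r_lo == self.r_hi:
                raise ValueError(f"linear {name} needs >= 2 occupied bins")
            self.k = 2
        else:
            self.k = len(occ)

    def values_at(self, v: np.ndarray, bins: np.ndarray, mids: np.ndarray) -> np.ndarray:
        if self.form == "constant":
            return np.full(len(bins), v[0])
        if self.form == "linear":
            w = (mids[bins - 1] - self.r_lo) / (self.r_hi - self.r_lo)
            return v[0] + (v[1] - v[0]) * w
        pos = {b: i for i, b in enumerate(self.occ)}
        return v[[pos[b] for b in bins]]

    def param_form(self, v: np.ndarray, n_bins: int) -> ParamForm:
        if self.form == "constant":
            return ParamForm("constant", (float(v[0]),))
        if self.form == "linear":
            slope = (v[1] - v[0]) / (self.r_hi - self.r_lo)
            return ParamForm("linear", (float(v[0] - slope * self.r_lo), float(slope)))
        full = np.full(n_bins, np.nan)
        full[self.occ - 1] = v
        return ParamForm("per_bin", tuple(full))


def fit_grouped(
    groups: Mapping[str, BinnedPairData],
    spec: GroupedSpec,
    pi: np.ndarray,
    config: OptimizerConfig | None = None,
) -> GroupedFitResult:
    """Jointly maximize the summed per-group likelihood under a GroupedSpec.

    kappa and t take one (form-shaped) value across all groups; omega lines
    follow the tie structure. Coordinates are (intercept, slope) per unique
    tie label, so a line tied across groups cannot be reparameterized by its
    endpoint values; instead, infeasible points (omega <= 0 at an occupied
    mid-point) incur a large finite penalty. Optima with the realistic
    positive-omega structure are interior and unaffected.
    """
    if config is None:
        config = OptimizerConfig()
    missing = set(spec.groups) - set(groups)
    if missing:
        raise ValueError(f"grouped spec references absent groups: {sorted(missing)}")
    datas = {g: groups[g] for g in spec.groups}
    n_bins = spec.n_bins
    for g, d in datas.items():
        if d.n_bins != n_bins:
            raise ValueError(f"group {g!r} binned with {d.n_bins} bins, spec has {n_bins}")
    pi = validate_frequencies(pi)
    log_pi = np.log(np.maximum(pi, _LOG_FLOOR))
    binning = next(iter(datas.values())).binning
    mids = binning.midpoints
    union_occ = np.array(sorted({b for d in datas.values() for b in d.occupied_bins}))
    if union_occ.size == 0:
        raise ValueError("no occupied RSA bins in any group")

    t_pack = _SharedPacking("t", spec.t_form, union_occ, mids)
    k_pack = _SharedPacking("kappa", spec.kappa_form, union_occ, mids)
    icpt_labels = sorted(set(spec.intercept_map.values()))
    slope_labels = sorted(set(spec.slope_map.values()))

    sl_t = slice(0, t_pack.k)
    sl_k = slice(sl_t.stop, sl_t.stop + k_pack.k)
    sl_i = slice(sl_k.stop, sl_k.stop + len(icpt_labels))
    sl_s = slice(sl_i.stop, sl_i.stop + len(slope_labels))
    size = sl_s.stop

    t_lo, t_hi = PARAM_BOUNDS["t"]
    k_lo, k_hi = PARAM_BOUNDS["kappa"]
    o_lo, o_hi = PARAM_BOUNDS["omega"]
    bounds = (
        [(t_lo, t_hi)] * t_pack.k
        + [(k_lo, k_hi)] * k_pack.k
        + [(o_lo, o_hi)] * len(icpt_labels)
        + [(-o_hi, o_hi)] * len(slope_labels)
    )

    group_occ = {g: np.array(d.occupied_bins, dtype=int) for g, d in datas.items()}
    icpt_idx = {lab: i for i, lab in enumerate(icpt_labels)}
    slope_idx = {lab: i for i, lab in enumerate(slope_labels)}

    def objective(x: np.ndarray) -> float:
        icpts, slopes = x[sl_i], x[sl_s]
        total = 0.0
        for g, d in datas.items():
            occ = group_occ[g]
            m = mids[occ - 1]
            omega = (
                icpts[icpt_idx[spec.intercept_map[g]]]
                + slopes[slope_idx[spec.slope_map[g]]] * m
            )
            if (omega <= 0).any():
                return 1e12 * (1.0 + float(np.maximum(-omega, 0).sum()))
            theta = {
                "omega": omega,
                "t": t_pack.values_at(x[sl_t], occ, mids),
                "kappa": k_pack.values_at(x[sl_k], occ, mids),
            }
            total += _bin_log_likelihood("GY94", theta, d, pi, log_pi)
        return -total

    x0_base = np.empty(size)
    x0_base[sl_t] = START_VALUES["t"]
    x0_base[sl_k] = START_VALUES["kappa"]
    x0_base[sl_i] = START_VALUES["omega"]
    x0_base[sl_s] = 0.05
    if config.init:
        for key, idx_map, sl in (
            ("omega0", icpt_idx, sl_i),
            ("omega1", slope_idx, sl_s),
        ):
            if key in config.init:
                for lab, val in dict(config.init[key]).items():  # type: ignore[arg-type]
                    x0_base[sl][idx_map[lab]] = val

    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best = None
    for start in range(config.n_starts):
        if start == 0:
            x0 = x0_base.copy()
        else:
            factor = 1.0 + config.jitter * (2.0 * rng.random(size) - 1.0)
            x0 = np.clip(x0_base * factor, lo, hi)
        res = scipy.optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    x = best.x
    omega_lines = {
        g: (
            float(x[sl_i][icpt_idx[spec.intercept_map[g]]]),
            float(x[sl_s][slope_idx[spec.slope_map[g]]]),
        )
        for g in spec.groups
    }
    df = spec.n_free_params()
    lnL = -float(best.fun)
    return GroupedFitResult(
        spec=spec,
        omega_lines=omega_lines,
        t_estimate=t_pack.param_form(x[sl_t], n_bins),
        kappa_estimate=k_pack.param_form(x[sl_k], n_bins),
        lnL=lnL,
        df=df,
        aic=aic(lnL, df),
        converged=bool(best.success),
    )
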