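"""Binned pairwise codon likelihood and maximum-likelihood fitting.

Sites are independent given their RSA bin. For a site in bin k with codon i
in the first sequence and j in the second, the likelihood contribution is
pi_i * P_k[i, j], where P_k = exp[t(r_k) Q(r_k)] (GY94) or the unit-time
transition matrix of the MG94 generator at bin k. Placing the stationary
root at one tip is equivalent, by reversibility, to the usual two-branch
formulation with an unobserved root, and is cheaper. The data reduce to
per-bin tables of ordered codon-pair counts; the log-likelihood is

    lnL = sum_k sum_{i,j} c_k(i,j) * log(pi_i * P_k[i,j]).

Optimization is bounded quasi-Newton (L-BFGS-B) with seeded multi-start.
Positivity of every evaluated parameter is enforced through the coordinates:
constants and per-bin values are box-bounded away from zero, and a linear
form is optimized as its values at the lowest and highest occupied bin
mid-points (a line positive at both extremes is positive at every mid-point
between them), then reported as (intercept, slope).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.optimize

from .codons import sense_codons
from .model import (
    ModelSpec,
    ParamForm,
    ReversibleExpm,
    gy94_rate_matrix,
    mg94_rate_matrix,
    validate_frequencies,
)
from .rsa import RsaBinning, SiteRsa

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-300

#: Box bounds on evaluated parameter values during optimization.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "omega": (1e-6, 100.0),
    "kappa": (1e-6, 100.0),
    "t": (1e-6, 50.0),
    "alpha": (1e-6, 50.0),
    "beta": (1e-6, 50.0),
}

#: Default starting values (constant across RSA) for each parameter.
START_VALUES: dict[str, float] = {
    "omega": 0.2,
    "kappa": 2.0,
    "t": 0.3,
    "alpha": 0.3,
    "beta": 0.06,
}


@dataclass
class BinnedPairData:
    """Sufficient statistics: per-bin counts of ordered sense-codon pairs."""

    binning: RsaBinning
    counts: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]
    n_sites_used: int
    n_excluded: int

    @property
    def n_bins(self) -> int:
        return self.binning.n

    @property
    def occupied_bins(self) -> tuple[int, ...]:
        return tuple(sorted(self.counts))

    def total_counts(self) -> int:
        return int(sum(c.sum() for _, _, c in self.counts.values()))


def bin_pair_counts(
    alignment, site_rsa: Sequence[SiteRsa], binning: RsaBinning
) -> BinnedPairData:
    """Tally ordered codon-pair counts per RSA bin from a pairwise alignment.

    ``alignment`` is any object with ``seq1`` and ``seq2`` attributes (or a
    2-tuple of strings). Sites with a gap or any non-ACGT character in
    either codon are excluded and counted in ``n_excluded``.
    """
    if hasattr(alignment, "seq1"):
        seq1, seq2 = alignment.seq1, alignment.seq2
    else:
        seq1, seq2 = alignment
    alphabet = sense_codons()
    n_codon_sites = len(seq1) // 3
    tallies: dict[int, dict[tuple[int, int], int]] = {}
    used = excluded = 0
    for sr in site_rsa:
        if not 1 <= sr.site <= n_codon_sites:
            raise ValueError(
                f"site {sr.site} outside alignment of {n_codon_sites} codon sites"
            )
        lo = 3 * (sr.site - 1)
        c1 = seq1[lo : lo + 3].upper().replace("U", "T")
        c2 = seq2[lo : lo + 3].upper().replace("U", "T")
        if c1 not in alphabet or c2 not in alphabet:
            excluded += 1
            continue
        pair = (alphabet.index[c1], alphabet.index[c2])
        tallies.setdefault(sr.bin, {})[pair] = tallies.setdefault(sr.bin, {}).get(pair, 0) + 1
        used += 1
    counts = {}
    for b, table in sorted(tallies.items()):
        pairs = sorted(table)
        ii = np.array([p[0] for p in pairs], dtype=int)
        jj = np.array([p[1] for p in pairs], dtype=int)
        cc = np.array([table[p] for p in pairs], dtype=float)
        counts[b] = (ii, jj, cc)
    if excluded:
        logger.info("excluded %d gapped/ambiguous codon sites", excluded)
    return BinnedPairData(
        binning=binning, counts=counts, n_sites_used=used, n_excluded=excluded
    )


# ---------------------------------------------------------------------------
# Log-likelihood
# ---------------------------------------------------------------------------

def _bin_log_likelihood(
    family: str,
    theta: Mapping[str, np.ndarray],
    data: BinnedPairData,
    pi: np.ndarray,
    log_pi: np.ndarray,
) -> float:
    """lnL given parameter values ``theta[name][idx]`` per occupied bin."""
    total = 0.0
    for idx, b in enumerate(data.occupied_bins):
        if family == "GY94":
            q = gy94_rate_matrix(theta["omega"][idx], theta["kappa"][idx], pi)
            t = theta["t"][idx]
        else:
            q = mg94_rate_matrix(
                theta["alpha"][idx], theta["beta"][idx], theta["kappa"][idx], pi
            )
            t = 1.0
        p = ReversibleExpm(q, pi).at(t)
        ii, jj, cc = data.counts[b]
        site_lik = np.maximum(pi[ii] * p[ii, jj], _LOG_FLOOR)
        total += float(cc @ np.log(site_lik))
    return total


def log_likelihood(
    spec: ModelSpec,
    params: Mapping[str, ParamForm],
    data: BinnedPairData,
    pi: np.ndarray,
) -> float:
    """Log-likelihood of binned pair counts under a parameterized model.

    ``params`` maps each of the family's parameter names to a ParamForm with
    values. Raises if any parameter evaluates non-positive at an occupied
    bin mid-point — the optimizer's coordinates are responsible for keeping
    iterates feasible.
    """
    pi = validate_frequencies(pi)
    occ = np.array(data.occupied_bins, dtype=int)
    if occ.size == 0:
        raise ValueError("no occupied RSA bins: nothing to evaluate")
    mids = data.binning.midpoints
    theta: dict[str, np.ndarray] = {}
    for name in spec.param_names:
        form = params[name]
        if form.form != spec.form_of(name):
            raise ValueError(
                f"form mismatch for {name}: spec says {spec.form_of(name)}, "
                f"got {form.form}"
            )
        vals = form.evaluate(mids, occ)
        if not (np.isfinite(vals).all() and (vals > 0).all()):
            raise ValueError(
                f"parameter {name} is non-positive at an occupied bin mid-point"
            )
        theta[name] = vals
    return _bin_log_likelihood(spec.family, theta, data, pi, np.log(pi))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class OptimizerConfig:
    """Multi-start bounded quasi-Newton settings.

    ``n_starts`` runs: the first from the default starting values, the rest
    jittered multiplicatively by +-``jitter`` with the seeded generator.
    ``init`` optionally overrides the default starting ParamForm values.
    """

    n_starts: int = 5
    seed: int = 0
    jitter: float = 0.5
    maxiter: int = 500
    init: dict[str, tuple[float, ...]] | None = None


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model specification."""

    spec: ModelSpec
    estimates: dict[str, ParamForm]
    lnL: float
    df: int
    aic: float
    converged: bool
    n_sites_used: int
    n_starts: int = 1

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "family": self.spec.family,
            "forms": dict(self.spec.forms),
            "n_bins": self.spec.n_bins,
            "estimates": {k: list(v.values) for k, v in self.estimates.items()},
            "lnL": self.lnL,
            "df": self.df,
            "AIC": self.aic,
            "converged": self.converged,
            "n_sites_used": self.n_sites_used,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


class _Packing:
    """Map between the free-parameter vector and per-bin parameter values."""

    def __init__(self, spec: ModelSpec, data: BinnedPairData):
        self.spec = spec
        self.occ = np.array(data.occupied_bins, dtype=int)
        mids = data.binning.midpoints
        self.mids_occ = mids[self.occ - 1]
        self.r_lo = float(self.mids_occ.min())
        self.r_hi = float(self.mids_occ.max())
        self.slices: dict[str, slice] = {}
        self.bounds: list[tuple[float, float]] = []
        pos = 0
        for name in spec.param_names:
            form = spec.form_of(name)
            lo, hi = PARAM_BOUNDS[name]
            if form == "constant":
                k = 1
            elif form == "linear":
                if self.r_lo == self.r_hi:
                    raise ValueError(
                        f"linear form for {name} needs >= 2 occupied bins"
                    )
                k = 2
            else:
                k = len(self.occ)
            self.slices[name] = slice(pos, pos + k)
            self.bounds.extend([(lo, hi)] * k)
            pos += k
        self.size = pos

    def start_vector(self, init: Mapping[str, tuple[float, ...]] | None) -> np.ndarray:
        x = np.empty(self.size)
        for name in self.spec.param_names:
            form = self.spec.form_of(name)
            sl = self.slices[name]
            if init is not None and name in init:
                if form == "constant":
                    x[sl] = init[name][0]
                elif form == "linear":
                    x0, x1 = init[name]
                    x[sl] = (x0 + x1 * self.r_lo, x0 + x1 * self.r_hi)
                else:
                    full = np.asarray(init[name], dtype=float)
                    x[sl] = full[self.occ - 1]
            else:
                x[sl] = START_VALUES[name]
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(x, lo, hi)

    def theta(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Evaluated parameter values at each occupied bin mid-point."""
        out = {}
        for name in self.spec.param_names:
            form = self.spec.form_of(name)
            v = x[self.slices[name]]
            if form == "constant":
                out[name] = np.full(len(self.occ), v[0])
            elif form == "linear":
                w = (self.mids_occ - self.r_lo) / (self.r_hi - self.r_lo)
                out[name] = v[0] + (v[1] - v[0]) * w
            else:
                out[name] = v
        return out

    def estimates(self, x: np.ndarray) -> dict[str, ParamForm]:
        """Fitted ParamForms: linear forms reported as (intercept, slope)."""
        out = {}
        for name in self.spec.param_names:
            form = self.spec.form_of(name)
            v = x[self.slices[name]]
            if form == "constant":
                out[name] = ParamForm("constant", (float(v[0]),))
            elif form == "linear":
                slope = (v[1] - v[0]) / (self.r_hi - self.r_lo)
                intercept = v[0] - slope * self.r_lo
                out[name] = ParamForm("linear", (float(intercept), float(slope)))
            else:
                full = np.full(self.spec.n_bins, np.nan)
                full[self.occ - 1] = v
                out[name] = ParamForm("per_bin", tuple(full))
        return out


def fit_model(
    spec: ModelSpec,
    data: BinnedPairData,
    pi: np.ndarray,
    config: OptimizerConfig | None = None,
) -> FitResult:
    """Maximize the binned pairwise log-likelihood over the free parameters.

    Multi-start L-BFGS-B: the best of ``config.n_starts`` runs is kept.
    df and AIC (= 2 df − 2 lnL) follow the form-based free-parameter count.
    """
    if config is None:
        config = OptimizerConfig()
    if not data.counts:
        raise ValueError("empty data: no occupied RSA bins")
    if spec.n_bins != data.n_bins:
        raise ValueError(
            f"spec has {spec.n_bins} bins but data were binned with {data.n_bins}"
        )
    pi = validate_frequencies(pi)
    log_pi = np.log(np.maximum(pi, _LOG_FLOOR))
    packing = _Packing(spec, data)

    def objective(x: np.ndarray) -> float:
        theta = packing.theta(x)
        return -_bin_log_likelihood(spec.family, theta, data, pi, log_pi)

    rng = np.random.default_rng(config.seed)
    x0_base = packing.start_vector(config.init)
    lo = np.array([b[0] for b in packing.bounds])
    hi = np.array([b[1] for b in packing.bounds])
    best = None
    failures = []
    for start in range(config.n_starts):
        if start == 0:
            x0 = x0_base
        else:
            factor = 1.0 + config.jitter * (2.0 * rng.random(packing.size) - 1.0)
            x0 = np.clip(x0_base * factor, lo, hi)
        try:
            res = scipy.optimize.minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=packing.bounds,
                options={"maxiter": config.maxiter},
            )
        except Exception as exc:  # pragma: no cover - diagnostic path
            failures.append(str(exc))
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {config.n_starts} optimization starts failed: {failures}"
        )
    estimates = packing.estimates(best.x)
    lnL = -float(best.fun)
    df = spec.n_free_params()
    return FitResult(
        spec=spec,
        estimates=estimates,
        lnL=lnL,
        df=df,
        aic=2.0 * df - 2.0 * lnL,
        converged=bool(best.success),
        n_sites_used=data.n_sites_used,
        n_starts=config.n_starts,
    )
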