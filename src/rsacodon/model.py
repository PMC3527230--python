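"""RSA-dependent GY94/MG94 rate matrices, F3x4 frequencies, matrix exponentials.

The instantaneous rate from sense codon i to j (i != j) under the GY94
family is

    Q_ij = 0                 if i and j differ at more than one nucleotide
         = pi_j              if synonymous transversion
         = kappa * pi_j      if synonymous transition
         = omega * pi_j      if nonsynonymous transversion
         = kappa*omega*pi_j  if nonsynonymous transition

with diagonal entries set so rows sum to zero. kappa, omega and the branch
length t may each be constant in RSA, linear in RSA, or estimated per RSA
bin; matrices are built at the bin mid-points r_k. The MG94 family replaces
(t, omega) by a synonymous rate alpha and a nonsynonymous rate beta, defined
here through the correspondence alpha = t, beta = t*omega: its generator
equals t times the GY94 generator and is integrated over unit time.

Q is reversible with stationary distribution pi, so P(t) = exp(tQ) can be
computed through a symmetric eigendecomposition (similarity by diag(sqrt(pi)));
:func:`transition_matrix` uses the general dense expm, and the likelihood
code uses the eigendecomposition fast path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.linalg

from .codons import NUCLEOTIDES, SubstitutionType, sense_codons, substitution_masks

FORMS = ("constant", "linear", "per_bin")

#: Free parameters per functional form; "per_bin" contributes n_bins.
FORM_DF = {"constant": 1, "linear": 2}

FAMILY_PARAMS = {"GY94": ("omega", "t", "kappa"), "MG94": ("alpha", "beta", "kappa")}


# ---------------------------------------------------------------------------
# Codon frequencies (F3x4)
# ---------------------------------------------------------------------------

def f3x4(sequences: Iterable[str]) -> np.ndarray:
    """Estimate sense-codon frequencies with the F3x4 model.

    Nucleotide frequencies are tallied separately at the three codon
    positions over all fully unambiguous (ACGT-only) codons of all supplied
    sequences; the frequency of codon j is the product of its positional
    nucleotide frequencies, restricted to the 61 sense codons and
    renormalized to sum to one.
    """
    counts = np.zeros((3, 4))
    nt_index = {nt: k for k, nt in enumerate(NUCLEOTIDES)}
    n_codons = 0
    for seq in sequences:
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3:
            raise ValueError(f"sequence length {len(seq)} not divisible by 3")
        for s in range(0, len(seq), 3):
            codon = seq[s : s + 3]
            if any(nt not in nt_index for nt in codon):
                continue
            n_codons += 1
            for pos, nt in enumerate(codon):
                counts[pos, nt_index[nt]] += 1
    if n_codons == 0:
        raise ValueError("no ungapped, unambiguous codons to estimate frequencies from")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    alphabet = sense_codons()
    pi = np.array(
        [
            freqs[0, nt_index[c[0]]] * freqs[1, nt_index[c[1]]] * freqs[2, nt_index[c[2]]]
            for c in alphabet.codons
        ]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("F3x4 product places no mass on sense codons")
    return pi / total


def uniform_frequencies() -> np.ndarray:
    """Uniform distribution over the 61 sense codons."""
    n = sense_codons().size
    return np.full(n, 1.0 / n)


def validate_frequencies(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (sense_codons().size,):
        raise ValueError(f"codon frequency vector must have length 61, got {pi.shape}")
    if (pi < 0).any() or not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("codon frequencies must be non-negative and sum to 1")
    return pi


# ---------------------------------------------------------------------------
# Parameter forms and model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamForm:
    """Functional form of one model parameter over RSA.

    ``values`` holds (x0,) for a constant, (intercept, slope) for a linear
    form, or one value per bin for a per-bin form (NaN marks bins that were
    never occupied by data and therefore carry no estimate).
    """

    form: str
    values: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"unknown parameter form {self.form!r}")
        if self.values is not None:
            object.__setattr__(self, "values", tuple(float(v) for v in self.values))
            n = len(self.values)
            if self.form == "constant" and n != 1:
                raise ValueError("constant form takes exactly 1 value")
            if self.form == "linear" and n != 2:
                raise ValueError("linear form takes (intercept, slope)")

    def evaluate(self, midpoints: np.ndarray, bins: np.ndarray | None = None) -> np.ndarray:
        """Evaluate the parameter at bin mid-points.

        ``bins`` gives 1-based bin indices for a per-bin form; by default all
        bins 1..len(midpoints) are evaluated.
        """
        if self.values is None:
            raise ValueError("parameter form has no values to evaluate")
        midpoints = np.asarray(midpoints, dtype=float)
        if bins is None:
            bins = np.arange(1, len(midpoints) + 1)
        bins = np.asarray(bins, dtype=int)
        if self.form == "constant":
            return np.full(len(bins), self.values[0])
        if self.form == "linear":
            x0, x1 = self.values
            return x0 + x1 * midpoints[bins - 1]
        vals = np.asarray(self.values, dtype=float)
        if len(vals) < bins.max():
            raise ValueError("per-bin form shorter than requested bin index")
        return vals[bins - 1]


@dataclass(frozen=True)
class ModelSpec:
    """Model family plus the RSA-dependency form of each parameter.

    GY94 parameters: omega, t, kappa. MG94 parameters: alpha, beta, kappa.
    """

    family: str
    forms: tuple[tuple[str, str], ...]
    n_bins: int = 20

    @staticmethod
    def make(family: str, n_bins: int = 20, **forms: str) -> "ModelSpec":
        family = family.upper()
        if family not in FAMILY_PARAMS:
            raise ValueError(f"unknown model family {family!r}")
        names = FAMILY_PARAMS[family]
        missing = set(names) - set(forms)
        extra = set(forms) - set(names)
        if missing or extra:
            raise ValueError(
                f"{family} takes forms for {names}; missing={missing}, extra={extra}"
            )
        for f in forms.values():
            if f not in FORMS:
                raise ValueError(f"unknown parameter form {f!r}")
        return ModelSpec(
            family=family,
            forms=tuple((name, forms[name]) for name in names),
            n_bins=n_bins,
        )

    @property
    def param_names(self) -> tuple[str, ...]:
        return FAMILY_PARAMS[self.family]

    def form_of(self, name: str) -> str:
        return dict(self.forms)[name]

    @property
    def name(self) -> str:
        inner = ",".join(f"{k}={v}" for k, v in self.forms)
        return f"{self.family}[{inner}]"

    def n_free_params(self) -> int:
        """Free-parameter count (df): constant 1, linear 2, per-bin n_bins.

        Codon frequencies are estimated once outside the likelihood and are
        not counted.
        """
        return sum(FORM_DF.get(f, self.n_bins) for _, f in self.forms)


# ---------------------------------------------------------------------------
# Rate matrices
# ---------------------------------------------------------------------------

def _require_positive(**params: float) -> None:
    for name, value in params.items():
        if not value > 0:
            raise ValueError(f"parameter {name} must be strictly positive, got {value}")


def gy94_rate_matrix(omega: float, kappa: float, pi: np.ndarray) -> np.ndarray:
    """GY94 generator: target-frequency rates with kappa/omega multipliers.

    Off-diagonal entries follow the class table in the module docstring; the
    matrix is NOT rescaled to one expected substitution per unit time — the
    branch length t multiplies Q directly, so its units are tied to the
    baseline rate of a synonymous transversion.
    """
    _require_positive(omega=omega, kappa=kappa)
    pi = validate_frequencies(pi)
    masks = substitution_masks()
    rates = (
        masks[SubstitutionType.SYN_TV] * 1.0
        + masks[SubstitutionType.SYN_TS] * kappa
        + masks[SubstitutionType.NONSYN_TV] * omega
        + masks[SubstitutionType.NONSYN_TS] * (kappa * omega)
    )
    q = rates * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def mg94_rate_matrix(alpha: float, beta: float, kappa: float, pi: np.ndarray) -> np.ndarray:
    """MG94 generator with synonymous rate alpha and nonsynonymous rate beta.

    Defined through the GY94 correspondence alpha = t, beta = t*omega: the
    matrix equals alpha (beta) times the target-frequency synonymous
    (nonsynonymous) GY94 entries and is integrated over unit time, so
    alpha = beta reduces to GY94 with omega = 1 at t = alpha.
    """
    _require_positive(alpha=alpha, beta=beta, kappa=kappa)
    pi = validate_frequencies(pi)
    masks = substitution_masks()
    rates = (
        masks[SubstitutionType.SYN_TV] * alpha
        + masks[SubstitutionType.SYN_TS] * (alpha * kappa)
        + masks[SubstitutionType.NONSYN_TV] * beta
        + masks[SubstitutionType.NONSYN_TS] * (beta * kappa)
    )
    q = rates * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def transition_matrix(q: np.ndarray, t: float) -> np.ndarray:
    """Finite-time transition matrix P = exp(t Q) via dense expm.

    Tiny negative entries from roundoff are clamped to zero and rows are
    renormalized to sum to one.
    """
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    p = scipy.linalg.expm(t * np.asarray(q, dtype=float))
    if (p < -1e-12).any():
        raise FloatingPointError("transition matrix has significantly negative entries")
    p = np.clip(p, 0.0, None)
    return p / p.sum(axis=1, keepdims=True)


class ReversibleExpm:
    """Matrix exponentials of a reversible generator via eigendecomposition.

    With D = diag(sqrt(pi)), S = D Q D^{-1} is symmetric for a pi-reversible
    Q; exp(tQ) = D^{-1} V exp(t Lambda) V^T D from one symmetric
    eigendecomposition, after which any t is a pair of 61x61 products.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        if (pi <= 0).any():
            raise ValueError("eigendecomposition path requires strictly positive pi")
        d = np.sqrt(pi)
        s = q * (d[:, None] / d[None, :])
        s = 0.5 * (s + s.T)
        self._eigvals, self._eigvecs = np.linalg.eigh(s)
        self._d = d

    def at(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"time must be non-negative, got {t}")
        v = self._eigvecs
        m = (v * np.exp(t * self._eigvals)) @ v.T
        p = m * (self._d[None, :] / self._d[:, None])
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)


def stationary_deviation(q: np.ndarray, pi: np.ndarray) -> float:
    """Max-norm of pi @ Q; zero (to roundoff) for a proper stationary pi."""
    return float(np.abs(pi @ q).max())
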