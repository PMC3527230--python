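"""Per-bin dN and dS derived from a fitted model, under two site definitions.

dN (dS) is the expected number of nonsynonymous (synonymous) substitutions
per nonsynonymous (synonymous) site. Expected substitution numbers come
from summing pi_i * Q_ij * t over the nonsynonymous (synonymous) entries of
the fitted generator. Site counts come in two flavors:

* physical sites — each of a codon's single-nucleotide mutations contributes
  1/3 of a site to the synonymous or nonsynonymous tally by the amino-acid
  comparison; mutations that would create a stop codon are excluded (the
  substitution process lives on sense codons).
* mutational opportunity — sites weighted by the probability that a mutation
  is synonymous under the fitted mutation process with selection switched
  off (omega = 1, fitted kappa), normalized to the same stop-adjusted total
  as the physical counts so the two definitions agree when kappa = 1 and
  codon frequencies are uniform.

Under the mutational-opportunity definition dN/dS reproduces omega(r_k)
exactly, tying the derived profiles back to the fitted rate-ratio line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codons import SubstitutionType, sense_codons, single_step_neighbors, substitution_masks
from .likelihood import FitResult
from .model import ModelSpec, gy94_rate_matrix, mg94_rate_matrix, validate_frequencies
from .rsa import RsaBinning

_SYN = (SubstitutionType.SYN_TS, SubstitutionType.SYN_TV)
_NONSYN = (SubstitutionType.NONSYN_TS, SubstitutionType.NONSYN_TV)


def _class_mask(kinds) -> np.ndarray:
    masks = substitution_masks()
    out = np.zeros_like(masks[SubstitutionType.MULTI])
    for k in kinds:
        out = out | masks[k]
    return out


def substitution_numbers(q: np.ndarray, pi: np.ndarray, t: float) -> tuple[float, float]:
    """Expected (synonymous, nonsynonymous) substitutions over time t.

    E_syn = t * sum over synonymous pairs of pi_i Q_ij, and likewise for the
    nonsynonymous pairs; together they exhaust the total flux −t Σ pi_i Q_ii.
    """
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    pi = validate_frequencies(pi)
    flux = pi[:, None] * q
    e_syn = t * float(flux[_class_mask(_SYN)].sum())
    e_nonsyn = t * float(flux[_class_mask(_NONSYN)].sum())
    return e_syn, e_nonsyn


@dataclass(frozen=True)
class SiteCounts:
    """Aggregated synonymous/nonsynonymous site counts (per average codon)."""

    S: float
    N: float

    @property
    def total(self) -> float:
        return self.S + self.N


def per_codon_physical_counts() -> tuple[np.ndarray, np.ndarray]:
    """Fractional (S, N) physical site counts for each of the 61 codons.

    Each of the 9 single-nucleotide mutations contributes 1/3 of a site;
    mutations to stop codons are dropped, so S + N = 3 − (stop neighbors)/3.
    """
    alphabet = sense_codons()
    s = np.zeros(alphabet.size)
    n = np.zeros(alphabet.size)
    for idx, codon in enumerate(alphabet.codons):
        for neighbor in single_step_neighbors(codon):
            if alphabet.aa_of[codon] == alphabet.aa_of[neighbor]:
                s[idx] += 1.0 / 3.0
            else:
                n[idx] += 1.0 / 3.0
    return s, n


def physical_sites(pi: np.ndarray) -> SiteCounts:
    """Frequency-weighted physical site counts per average codon."""
    pi = validate_frequencies(pi)
    s, n = per_codon_physical_counts()
    return SiteCounts(S=float(pi @ s), N=float(pi @ n))


def mutational_opportunity_sites(kappa: float, pi: np.ndarray) -> SiteCounts:
    """Rate-weighted site counts under the neutralized fitted process.

    Builds the generator with the fitted kappa and omega = 1 and splits the
    total stationary flux into synonymous and nonsynonymous shares; the
    shares are scaled to the stop-adjusted per-codon total of the physical
    counts, making the counts invariant to the overall scale of Q.
    """
    pi = validate_frequencies(pi)
    q_neutral = gy94_rate_matrix(1.0, kappa, pi)
    flux = pi[:, None] * q_neutral
    s_flux = float(flux[_class_mask(_SYN)].sum())
    n_flux = float(flux[_class_mask(_NONSYN)].sum())
    total = physical_sites(pi).total
    scale = total / (s_flux + n_flux)
    return SiteCounts(S=s_flux * scale, N=n_flux * scale)


def rate_profile(fit: FitResult, binning: RsaBinning, pi: np.ndarray) -> pd.DataFrame:
    """Per-bin dN/dS profile of a fitted model under both site definitions.

    Returns a DataFrame with one row per bin at which every parameter has an
    estimate, columns: bin, r, omega, dN_mut, dS_mut, dN_phys, dS_phys.
    """
    pi = validate_frequencies(pi)
    spec = fit.spec
    mids = binning.midpoints
    bins = np.arange(1, binning.n + 1)
    evaluated = {
        name: fit.estimates[name].evaluate(mids, bins) for name in spec.param_names
    }
    phys = physical_sites(pi)
    rows = []
    for k in bins:
        idx = k - 1
        vals = {name: evaluated[name][idx] for name in spec.param_names}
        if any(not np.isfinite(v) for v in vals.values()):
            continue  # per-bin parameter with no data in this bin
        if spec.family == "GY94":
            q = gy94_rate_matrix(vals["omega"], vals["kappa"], pi)
            t = vals["t"]
            omega_k = vals["omega"]
        else:
            q = mg94_rate_matrix(vals["alpha"], vals["beta"], vals["kappa"], pi)
            t = 1.0
            omega_k = vals["beta"] / vals["alpha"]
        e_syn, e_nonsyn = substitution_numbers(q, pi, t)
        mut = mutational_opportunity_sites(vals["kappa"], pi)
        rows.append(
            {
                "bin": int(k),
                "r": float(mids[idx]),
                "omega": float(omega_k),
                "dN_mut": e_nonsyn / mut.N,
                "dS_mut": e_syn / mut.S,
                "dN_phys": e_nonsyn / phys.N,
                "dS_phys": e_syn / phys.S,
            }
        )
    return pd.DataFrame(rows)
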