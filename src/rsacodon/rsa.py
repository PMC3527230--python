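"""Relative solvent accessibility: ASA normalization, binning, DSSP ingestion.

RSA is the per-residue solvent-accessible surface area (ASA, in Å²) divided
by the residue's maximum accessibility in an extended Gly-X-Gly peptide,
clamped to [0, 1]. RSA values are discretized into n evenly spaced bins on
[0, 1], each represented by its mid-point r_k; model parameters are
evaluated at these mid-points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Maximum solvent accessibility (Å²) of residue X in an extended Gly-X-Gly
#: peptide; theoretical values from Tien et al. (2013). Used as the default
#: normalization table; any 20-entry positive table may be substituted.
MAX_ASA_GLY_X_GLY: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


def asa_to_rsa(asa: float, aa: str, table: Mapping[str, float] | None = None) -> float:
    """Normalize an absolute ASA (Å²) to RSA in [0, 1].

    Values above the tabulated maximum (possible for distorted residues)
    are clamped to 1.0.
    """
    if table is None:
        table = MAX_ASA_GLY_X_GLY
    aa = aa.upper()
    if aa not in table:
        raise ValueError(f"no maximum-ASA value for residue {aa!r}")
    if asa < 0:
        raise ValueError(f"negative ASA: {asa}")
    return min(asa / table[aa], 1.0)


@dataclass(frozen=True)
class RsaBinning:
    """n evenly spaced bins on [0, 1] with mid-point representatives r_k."""

    n: int
    edges: np.ndarray
    midpoints: np.ndarray

    def __post_init__(self):
        self.edges.setflags(write=False)
        self.midpoints.setflags(write=False)


def make_binning(n: int) -> RsaBinning:
    """Build ``n`` equal-width RSA bins on [0, 1] (``n`` >= 2)."""
    if n < 2:
        raise ValueError(f"need at least 2 RSA bins, got {n}")
    edges = np.linspace(0.0, 1.0, n + 1)
    midpoints = 0.5 * (edges[:-1] + edges[1:])
    return RsaBinning(n=n, edges=edges, midpoints=midpoints)


def assign_bins(rsa_values: Sequence[float], binning: RsaBinning) -> np.ndarray:
    """Map RSA values in [0, 1] to 1-based bin indices.

    Bins are half-open [edge_k, edge_{k+1}) with the final bin closed on the
    right, so rsa = 1.0 maps to bin n. Values outside [0, 1] are rejected;
    callers clamp first (see :func:`asa_to_rsa`).
    """
    values = np.asarray(rsa_values, dtype=float)
    if values.size and (values.min() < 0.0 or values.max() > 1.0):
        bad = values[(values < 0.0) | (values > 1.0)][0]
        raise ValueError(f"RSA value outside [0, 1]: {bad}")
    idx = np.minimum(np.floor(values * binning.n).astype(int), binning.n - 1)
    return idx + 1


@dataclass(frozen=True)
class SiteRsa:
    """RSA of one codon site: 1-based alignment position, value, bin index."""

    site: int
    rsa: float
    bin: int


def site_rsa_list(
    sites: Sequence[int], rsa_values: Sequence[float], binning: RsaBinning
) -> list[SiteRsa]:
    """Clamp RSA values to [0, 1], assign bins, and build SiteRsa records."""
    values = np.clip(np.asarray(rsa_values, dtype=float), 0.0, 1.0)
    bins = assign_bins(values, binning)
    return [
        SiteRsa(site=int(s), rsa=float(v), bin=int(b))
        for s, v, b in zip(sites, values, bins)
    ]


def parse_dssp_asa(path: str) -> dict[tuple[str, int], tuple[str, float]]:
    """Read a DSSP output file and return (chain, residue number) -> (aa, ASA).

    Reads the fixed-column DSSP residue block (residue number in columns
    6-10, chain id in column 12, amino acid in column 14, ACC — absolute
    solvent accessibility in Å² — in columns 35-38). Chain-break records
    ('!') are skipped; lowercase amino-acid letters (disulfide-bonded
    cysteines) are mapped to 'C'. Unparseable residue lines are skipped with
    a logged count; a file without the residue-block header is rejected.
    """
    with open(path) as fh:
        lines = fh.readlines()
    start = None
    for k, line in enumerate(lines):
        fields = line.split()
        if len(fields) >= 2 and fields[1] == "RESIDUE":
            start = k + 1
            break
    if start is None:
        raise ValueError(
            f"DSSP file {path!r} is malformed: no '#  RESIDUE' header line"
        )
    out: dict[tuple[str, int], tuple[str, float]] = {}
    skipped = 0
    for line in lines[start:]:
        if not line.strip():
            continue
        if len(line) > 13 and line[13] == "!":  # chain break / discontinuity
            continue
        try:
            resnum = int(line[5:10])
            chain = line[11]
            aa = line[13]
            acc = float(line[34:38])
        except (ValueError, IndexError):
            skipped += 1
            continue
        if aa.islower():  # SS-bridge cysteine labels a-z
            aa = "C"
        out[(chain, resnum)] = (aa, acc)
    if skipped:
        logger.warning("skipped %d unparseable DSSP residue lines", skipped)
    if not out:
        raise ValueError(f"DSSP file {path!r} contains no resolved residues")
    return out
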