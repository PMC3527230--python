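"""Shared fixtures: codon frequencies, binnings, and a synthetic DSSP file."""

from __future__ import annotations

import numpy as np
import pytest

import rsacodon as rc


@pytest.fixture(scope="session")
def pi_uniform() -> np.ndarray:
    return rc.uniform_frequencies()


@pytest.fixture(scope="session")
def binning20() -> rc.RsaBinning:
    return rc.make_binning(20)


@pytest.fixture(scope="session")
def binning4() -> rc.RsaBinning:
    return rc.make_binning(4)


def dssp_line(idx: int, resnum: int, chain: str, aa: str, acc: float) -> str:
    """One residue record in DSSP fixed-column layout (only the fields the
    reader uses are populated)."""
    line = [" "] * 40
    line[0:5] = f"{idx:5d}"
    line[5:10] = f"{resnum:5d}"
    line[11] = chain
    line[13] = aa
    line[34:38] = f"{int(round(acc)):4d}"
    return "".join(line)


def dssp_break_line(idx: int) -> str:
    line = [" "] * 40
    line[0:5] = f"{idx:5d}"
    line[13] = "!"
    return "".join(line)


DSSP_HEADER = (
    "==== Secondary Structure Definition by the program DSSP ====\n"
    "REFERENCE W. KABSCH AND C.SANDER\n"
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
    "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA\n"
)


@pytest.fixture()
def dssp_file(tmp_path):
    """Synthetic two-residue DSSP fixture with a chain break in the middle."""
    body = "\n".join(
        [
            dssp_line(1, 1, "A", "M", 120.0),
            dssp_break_line(2),
            dssp_line(3, 2, "A", "G", 52.0),
        ]
    )
    path = tmp_path / "toy.dssp"
    path.write_text(DSSP_HEADER + body + "\n")
    return path
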