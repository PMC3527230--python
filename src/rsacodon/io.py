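"""Readers and writers for the package's exchange formats.

FASTA pairwise codon alignments (exactly two records, equal lengths
divisible by 3), site-RSA TSV tables (1-based codon ``site`` plus either a
``rsa`` column or ``asa`` + ``aa`` columns triggering Gly-X-Gly
normalization), and DSSP-derived RSA tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .rsa import (
    MAX_ASA_GLY_X_GLY,
    RsaBinning,
    SiteRsa,
    asa_to_rsa,
    parse_dssp_asa,
    site_rsa_list,
)


@dataclass(frozen=True)
class PairAlignment:
    """A validated two-sequence codon alignment."""

    name1: str
    name2: str
    seq1: str
    seq2: str

    @property
    def n_codon_sites(self) -> int:
        return len(self.seq1) // 3


def read_pair_fasta(path: str) -> PairAlignment:
    """Read and validate a pairwise codon alignment from FASTA.

    Requires exactly 2 records of equal length divisible by 3; sequences are
    upper-cased and U is mapped to T.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) != 2:
        raise ValueError(
            f"pairwise alignment requires exactly 2 FASTA records, got {len(records)}"
        )
    seqs = [str(r.seq).upper().replace("U", "T") for r in records]
    if len(seqs[0]) != len(seqs[1]):
        raise ValueError(
            f"aligned sequences differ in length: {len(seqs[0])} vs {len(seqs[1])}"
        )
    if len(seqs[0]) % 3:
        raise ValueError(f"alignment length {len(seqs[0])} not divisible by 3")
    return PairAlignment(
        name1=records[0].id, name2=records[1].id, seq1=seqs[0], seq2=seqs[1]
    )


def read_site_rsa(
    path: str,
    binning: RsaBinning,
    max_asa: Mapping[str, float] | None = None,
) -> list[SiteRsa]:
    """Read a site-RSA TSV into binned SiteRsa records.

    The table needs a 1-based ``site`` column and either ``rsa`` (used
    directly, clamped to [0, 1]) or ``asa`` + ``aa`` (normalized through the
    max-ASA table). Rows with missing values are dropped (sites without
    structural information are excluded from the likelihood).
    """
    df = pd.read_csv(path, sep="\t")
    if "site" not in df.columns:
        raise ValueError(f"{path}: site-RSA table needs a 'site' column")
    if "rsa" in df.columns:
        df = df.dropna(subset=["site", "rsa"])
        rsa = df["rsa"].astype(float)
    elif {"asa", "aa"} <= set(df.columns):
        df = df.dropna(subset=["site", "asa", "aa"])
        rsa = pd.Series(
            [
                asa_to_rsa(float(a), str(aa), max_asa)
                for a, aa in zip(df["asa"], df["aa"])
            ],
            index=df.index,
        )
    else:
        raise ValueError(
            f"{path}: need either an 'rsa' column or 'asa' + 'aa' columns"
        )
    return site_rsa_list(df["site"].astype(int).tolist(), rsa.tolist(), binning)


def dssp_to_site_rsa(
    dssp_path: str,
    chain: str | None = None,
    offset: int = 0,
    max_asa: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Convert a DSSP output file to a site-RSA table.

    Residue numbers map to codon sites as ``site = residue number + offset``
    (homology mapping between sequence and structure is out of scope; the
    caller supplies any needed offset). Returns a DataFrame with columns
    site, aa, asa, rsa.
    """
    records = parse_dssp_asa(dssp_path)
    if max_asa is None:
        max_asa = MAX_ASA_GLY_X_GLY
    rows = []
    for (ch, resnum), (aa, acc) in sorted(records.items()):
        if chain is not None and ch != chain:
            continue
        if aa not in max_asa:  # e.g. 'X' unknown residues
            continue
        rows.append(
            {
                "site": resnum + offset,
                "aa": aa,
                "asa": acc,
                "rsa": asa_to_rsa(acc, aa, max_asa),
            }
        )
    if not rows:
        raise ValueError(f"no usable residues in {dssp_path!r} (chain={chain!r})")
    return pd.DataFrame(rows)
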