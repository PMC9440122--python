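"""Per-CpG bisulfite and TAB-seq base calling and their combination.

Cloned amplicon sequences are aligned to the untreated reference with a
bisulfite-aware global alignment (clone T opposite reference C scores as a
match, since conversion turns unprotected C into T).  At each reference
CpG the clone base is called C (protected) or T (converted); the per-clone
conversion rate at non-CpG cytosines serves as quality control, and clones
converting fewer than 95% of them are excluded from site estimates.

Chemistry: in bisulfite sequencing (BS) both 5mC and 5hmC read as C, so
the per-site percent C estimates 5mC + 5hmC; in TAB-seq only
glucosyl-protected 5hmC reads as C, so percent C estimates 5hmC.  The 5mC
level per site is the (clipped) difference of the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.SeqRecord import SeqRecord

from .simulate import cpg_positions

GAP = "-"


class AlignmentError(ValueError):
    """Clone/reference alignment problem (e.g. mismatched site sets)."""


@dataclass
class RejectedClone:
    clone_id: str
    reason: str
    identity: float


@dataclass
class CloneMatrix:
    """Clone × CpG-site base calls plus per-clone conversion QC.

    ``calls[i, j]`` is 'C', 'T' or '-' for clone i at CpG site j (reference
    coordinates in ``cpg_positions``).  ``retained`` marks clones passing
    the non-CpG conversion threshold; rejected alignments are listed
    separately.
    """

    calls: np.ndarray
    cpg_positions: List[int]
    chemistry: str
    clone_ids: List[str]
    conversion_rates: np.ndarray
    retained: np.ndarray
    rejected: List[RejectedClone] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.chemistry not in ("BS", "TAB"):
            raise ValueError(f"unknown chemistry {self.chemistry!r}")
        if self.calls.shape != (len(self.clone_ids),
                                len(self.cpg_positions)):
            raise ValueError("calls shape mismatch")

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


def _bisulfite_aligner() -> PairwiseAligner:
    """Global aligner with free end gaps; clone T vs reference C is a match."""
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            m[a, b] = 1.0 if a == b else -1.0
    m["C", "T"] = 1.0  # reference C read as T after conversion
    for a in alphabet:
        m[a, "N"] = m["N", a] = 0.0
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    for attr in (
        "open_end_insertion_score",
        "extend_end_insertion_score",
        "open_end_deletion_score",
        "extend_end_deletion_score",
    ):
        setattr(aligner, attr, 0.0)
    return aligner


def _ref_to_clone_map(alignment) -> Dict[int, str]:
    """Map each aligned reference position to the clone base (or gap)."""
    ref = str(alignment.target)
    clone = str(alignment.query)
    mapping: Dict[int, str] = {}
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for k in range(t1 - t0):
            mapping[t0 + k] = clone[q0 + k]
    _ = ref
    return mapping


def call_clones(
    clones: Union[str, Path, Iterable[SeqRecord]],
    reference: str,
    chemistry: str,
    min_conversion: float = 0.95,
    min_identity: float = 0.80,
) -> CloneMatrix:
    """Align clones to the reference and call C/T at every CpG site.

    ``clones`` may be a FASTA path or SeqRecord iterable.  Alignments with
    identity below ``min_identity`` (bisulfite-aware) are rejected; clones
    whose non-CpG cytosine conversion rate falls below ``min_conversion``
    are kept in the matrix but flagged as not retained (incomplete
    conversion artifacts).
    """
    if isinstance(clones, (str, Path)):
        records = list(SeqIO.parse(str(clones), "fasta"))
    else:
        records = list(clones)
    ref = reference.upper()
    sites = cpg_positions(ref)
    if not sites:
        raise AlignmentError("reference contains no CpG site")
    non_cpg_c = [
        i for i, b in enumerate(ref) if b == "C" and i not in set(sites)
    ]
    aligner = _bisulfite_aligner()

    calls_rows: List[List[str]] = []
    ids: List[str] = []
    conv_rates: List[float] = []
    rejected: List[RejectedClone] = []
    for rec in records:
        clone_seq = str(rec.seq).upper()
        alignment = aligner.align(ref, clone_seq)[0]
        mapping = _ref_to_clone_map(alignment)
        matches = sum(
            1
            for i, b in mapping.items()
            if b == ref[i] or (ref[i] == "C" and b == "T")
        )
        # identity over the full reference length, so clones aligning only
        # a short stretch (free end gaps) cannot score high
        identity = matches / len(ref)
        if identity < min_identity:
            rejected.append(
                RejectedClone(rec.id, "low alignment identity", identity)
            )
            continue
        row = []
        for p in sites:
            base = mapping.get(p, GAP)
            row.append(base if base in ("C", "T") else GAP)
        n_c = n_t = 0
        for p in non_cpg_c:
            base = mapping.get(p, GAP)
            if base == "C":
                n_c += 1
            elif base == "T":
                n_t += 1
        rate = n_t / (n_c + n_t) if (n_c + n_t) else 0.0
        calls_rows.append(row)
        ids.append(rec.id)
        conv_rates.append(rate)

    conv = np.array(conv_rates, dtype=float)
    calls = (
        np.array(calls_rows, dtype=object)
        if calls_rows
        else np.empty((0, len(sites)), dtype=object)
    )
    return CloneMatrix(
        calls=calls,
        cpg_positions=sites,
        chemistry=chemistry,
        clone_ids=ids,
        conversion_rates=conv,
        retained=conv >= min_conversion,
        rejected=rejected,
    )


def _wilson_interval(k: int, n: int) -> tuple:
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def site_percentages(matrix: CloneMatrix) -> pd.DataFrame:
    """Percent C per CpG site over retained clones, with Wilson 95% CI.

    Gaps are excluded; a site with no informative clone gets NaN.
    """
    if matrix.n_retained < 1:
        raise ValueError("no retained clones")
    calls = matrix.calls[matrix.retained]
    rows = []
    for j, pos in enumerate(matrix.cpg_positions):
        col = calls[:, j]
        n_c = int(np.sum(col == "C"))
        n_t = int(np.sum(col == "T"))
        n = n_c + n_t
        if n == 0:
            rows.append((pos, np.nan, 0, np.nan, np.nan))
            continue
        lo, hi = _wilson_interval(n_c, n)
        rows.append((pos, 100.0 * n_c / n, n, 100.0 * lo, 100.0 * hi))
    out = pd.DataFrame(
        rows, columns=["site", "percent_c", "n", "ci_low", "ci_high"]
    )
    out["chemistry"] = matrix.chemistry
    return out


@dataclass
class SiteModificationEstimate:
    site: int
    bs_percent: float  # 5mC + 5hmC
    tab_percent: float  # 5hmC
    mc_percent: float
    clipped: bool
    n_bs: int
    n_tab: int


def combine_bs_tab(
    bs_sites: pd.DataFrame, tab_sites: pd.DataFrame
) -> List[SiteModificationEstimate]:
    """Per-site 5mC / 5hmC split from matched BS and TAB site tables.

    TAB percent C is the 5hmC level; 5mC is the BS percent minus the TAB
    percent, floored at 0 with a clip flag (sampling noise can drive the
    raw difference negative).
    """
    if list(bs_sites["site"]) != list(tab_sites["site"]):
        raise AlignmentError("BS and TAB site sets differ")
    out = []
    for (_, b), (_, t) in zip(bs_sites.iterrows(), tab_sites.iterrows()):
        raw_mc = b["percent_c"] - t["percent_c"]
        mc = max(raw_mc, 0.0)
        out.append(
            SiteModificationEstimate(
                site=int(b["site"]),
                bs_percent=float(b["percent_c"]),
                tab_percent=float(t["percent_c"]),
                mc_percent=float(mc),
                clipped=raw_mc < 0,
                n_bs=int(b["n"]),
                n_tab=int(t["n"]),
            )
        )
    return out


def estimates_frame(
    estimates: Sequence[SiteModificationEstimate],
) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in estimates])
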