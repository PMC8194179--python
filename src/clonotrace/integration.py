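"""Multi-contrast differential-expression integration.

Five DE contrasts are combined: metastasis vs primary tumor (``m``),
invasive vs weakly invasive subclones (``c``), LCK siRNA knockdown (``s``),
LCK inhibitor treatment (``l``) and dasatinib treatment (``d``). A gene
that drives invasiveness downstream of LCK should move the *same* way under
knockdown and both inhibitors and the *opposite* way in metastasis and
invasive clones; the LCK correlation score (LCS) formalizes this:

    LCS = sign(log2FC_m) + sign(log2FC_c)
          - [sign(log2FC_s) + sign(log2FC_l) + sign(log2FC_d)]

so the maximally LCK-consistent pattern (up in m and c, down in s, l, d)
scores +5 and its mirror image -5. Genes are filtered for recurrence
(significant in >= 3 of 5 contrasts at FDR < 0.05) and sorted by |LCS|.
The module also provides the two-dataset concordant overlap (same sign,
FDR < 0.05, log2CPM > 2 in both), candidate Venn lists, a sign-corrected
mean log2FC for heat-map display, and recurrent-process filtering over
overrepresentation results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import ORAResult

__all__ = [
    "DATASETS",
    "DETable",
    "CandidateLists",
    "read_de_table",
    "write_de_table",
    "concordant_overlap",
    "build_integration_matrix",
    "filter_recurrent",
    "lck_correlation_score",
    "mean_signed_log2fc",
    "sort_by_lcs",
    "candidate_venn",
    "recurrent_processes",
    "process_group_shares",
    "read_gmt",
]

#: Contrast labels: metastasis, clones, siRNA, LCK inhibitor, dasatinib.
DATASETS = ("m", "c", "s", "l", "d")

#: Contrasts in which an LCK-driven gene moves with invasiveness ...
INVASION_DATASETS = ("m", "c")
#: ... and those in which it moves with LCK loss of function.
INHIBITION_DATASETS = ("s", "l", "d")

_REQUIRED_COLUMNS = ("gene", "log2fc", "p_value", "fdr", "log2cpm")


@dataclass(frozen=True)
class DETable:
    """One contrast's differential-expression results (one row per gene)."""

    dataset_id: str
    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"DE table missing columns: {missing}")
        if df["gene"].duplicated().any():
            dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate genes in DE table: {dups[:5]}")
        for col in ("p_value", "fdr"):
            bad = (df[col] < 0) | (df[col] > 1)
            if bad.any():
                raise ValueError(f"{col} outside [0, 1] for "
                                 f"{df.loc[bad, 'gene'].tolist()[:5]}")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.data["gene"])


@dataclass(frozen=True)
class CandidateLists:
    """The two Venn candidate lists; disjoint by construction."""

    up_in_invasion_down_on_inhibition: list[str] = field(default_factory=list)
    down_in_invasion_up_on_inhibition: list[str] = field(default_factory=list)


def read_de_table(path, dataset_id: str) -> DETable:
    """Read a TSV with columns gene, log2fc, p_value, fdr, log2cpm."""
    df = pd.read_csv(path, sep="\t")
    return DETable(dataset_id=dataset_id, data=df)


def write_de_table(table: DETable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def concordant_overlap(a: DETable, b: DETable,
                       fdr_max: float = 0.05,
                       min_log2cpm: float = 2.0) -> tuple[list[str], list[str]]:
    """Genes deregulated the same way in both contrasts.

    A gene qualifies when, in *both* tables, fdr < ``fdr_max``,
    log2cpm > ``min_log2cpm`` (strict, filtering lowly expressed genes),
    and the log2FC signs are equal and nonzero. Returns (up, down) lists,
    sorted alphabetically.
    """
    m = a.data.merge(b.data, on="gene", suffixes=("_a", "_b"))
    sig = (m["fdr_a"] < fdr_max) & (m["fdr_b"] < fdr_max)
    abundant = (m["log2cpm_a"] > min_log2cpm) & (m["log2cpm_b"] > min_log2cpm)
    up = sig & abundant & (m["log2fc_a"] > 0) & (m["log2fc_b"] > 0)
    down = sig & abundant & (m["log2fc_a"] < 0) & (m["log2fc_b"] < 0)
    return sorted(m.loc[up, "gene"]), sorted(m.loc[down, "gene"])


def build_integration_matrix(tables: Sequence[DETable],
                             fdr_max: float = 0.05) -> pd.DataFrame:
    """Align the five contrasts on a common gene index.

    Returns a frame indexed by gene with ``log2fc_<id>`` and ``fdr_<id>``
    per contrast (NaN where the gene was not tested in that contrast —
    absent genes count as non-significant, never as log2FC 0), plus
    ``n_significant``, ``lcs`` and ``mean_signed_log2fc``.
    """
    ids = [t.dataset_id for t in tables]
    if sorted(ids) != sorted(DATASETS):
        raise ValueError(
            f"need exactly the five contrasts {DATASETS}, got {ids}")
    pieces = []
    for t in tables:
        piece = t.data.set_index("gene")[["log2fc", "fdr"]]
        piece.columns = [f"log2fc_{t.dataset_id}", f"fdr_{t.dataset_id}"]
        pieces.append(piece)
    mat = pd.concat(pieces, axis=1, join="outer").sort_index()
    fdr_cols = [f"fdr_{d}" for d in DATASETS]
    mat["n_significant"] = (mat[fdr_cols] < fdr_max).sum(axis=1).astype(int)
    if mat.empty:
        mat["lcs"] = pd.Series(dtype=int)
        mat["mean_signed_log2fc"] = pd.Series(dtype=float)
    else:
        mat["lcs"] = mat.apply(lck_correlation_score, axis=1)
        mat["mean_signed_log2fc"] = mat.apply(mean_signed_log2fc, axis=1)
    return mat


def filter_recurrent(matrix: pd.DataFrame, min_datasets: int = 3) -> pd.DataFrame:
    """Keep genes significantly deregulated in >= min_datasets contrasts."""
    return matrix[matrix["n_significant"] >= min_datasets]


def _sign(x) -> int:
    if pd.isna(x):
        return 0
    return int(np.sign(x))


def lck_correlation_score(gene_row: Mapping[str, float]) -> int:
    """Signed concordance of one gene's direction pattern with LCK drive.

    +5 for the maximally LCK-consistent pattern (up in metastasis and
    invasive clones, down under knockdown and both inhibitors); -5 for the
    mirror; 0 when directions carry no net LCK signal. Missing contrasts
    contribute 0.
    """
    inv = sum(_sign(gene_row.get(f"log2fc_{d}")) for d in INVASION_DATASETS)
    inh = sum(_sign(gene_row.get(f"log2fc_{d}")) for d in INHIBITION_DATASETS)
    return inv - inh


def mean_signed_log2fc(gene_row: Mapping[str, float]) -> float:
    """Mean log2FC over present contrasts with m and c negated.

    Negating the invasion contrasts puts all five on the "response to LCK
    loss" axis, so a coherent gene has a large-magnitude mean. NaN when no
    contrast is present.
    """
    vals = []
    for d in DATASETS:
        v = gene_row.get(f"log2fc_{d}")
        if v is not None and not pd.isna(v):
            vals.append(-v if d in INVASION_DATASETS else v)
    return float(np.mean(vals)) if vals else float("nan")


def sort_by_lcs(matrix: pd.DataFrame) -> pd.DataFrame:
    """Order genes by |LCS| (descending), then mean |log2FC| (descending),
    then gene label — the display order of the integration heat map."""
    fc_cols = [f"log2fc_{d}" for d in DATASETS]
    key = pd.DataFrame({
        "abs_lcs": matrix["lcs"].abs().to_numpy(),
        "mean_abs_fc": matrix[fc_cols].abs().mean(axis=1).to_numpy(),
        "label": matrix.index.to_numpy(),
    })
    order = matrix.index[key.sort_values(
        ["abs_lcs", "mean_abs_fc", "label"],
        ascending=[False, False, True]).index]
    return matrix.loc[order]


def candidate_venn(matrix: pd.DataFrame,
                   fdr_max: float = 0.05) -> CandidateLists:
    """The two candidate gene lists of the integration Venn diagrams.

    List 1: significantly up (fdr < fdr_max, log2FC > 0) in metastasis or
    invasive clones AND significantly down in at least one of knockdown /
    inhibitor / dasatinib. List 2 is the mirror image. A gene matching both
    patterns is dropped from both with a warning, keeping the lists disjoint.
    """
    def sig_dir(row, d, positive):
        fc, q = row.get(f"log2fc_{d}"), row.get(f"fdr_{d}")
        if pd.isna(fc) or pd.isna(q) or q >= fdr_max:
            return False
        return fc > 0 if positive else fc < 0

    up_list, down_list, both = [], [], []
    for gene, row in matrix.iterrows():
        inv_up = any(sig_dir(row, d, True) for d in INVASION_DATASETS)
        inv_down = any(sig_dir(row, d, False) for d in INVASION_DATASETS)
        inh_up = any(sig_dir(row, d, True) for d in INHIBITION_DATASETS)
        inh_down = any(sig_dir(row, d, False) for d in INHIBITION_DATASETS)
        p1 = inv_up and inh_down
        p2 = inv_down and inh_up
        if p1 and p2:
            both.append(gene)
        elif p1:
            up_list.append(gene)
        elif p2:
            down_list.append(gene)
    if both:
        warnings.warn(f"genes matching both Venn patterns dropped: {both}")
    return CandidateLists(sorted(up_list), sorted(down_list))


def recurrent_processes(ora_runs: Sequence[Sequence[ORAResult]],
                        min_fold: float = 3.0,
                        min_analyses: int = 2,
                        fdr_max: float = 0.05) -> list[str]:
    """Terms significantly overrepresented (> min_fold) in >= min_analyses
    runs — the recurrent downstream processes across inhibition contrasts."""
    if len(ora_runs) < 2:
        raise ValueError("need at least 2 overrepresentation runs")
    counts: dict[str, int] = {}
    for run in ora_runs:
        for res in run:
            if res.fdr < fdr_max and res.fold_enrichment > min_fold:
                counts[res.term_id] = counts.get(res.term_id, 0) + 1
    return sorted(t for t, c in counts.items() if c >= min_analyses)


def process_group_shares(terms: Sequence[str],
                         group_map: Mapping[str, str]) -> dict[str, float]:
    """Fraction of terms per thematic group; unmapped terms fall to 'other'.

    Shares sum to 1 over the returned groups.
    """
    if not terms:
        return {}
    counts: dict[str, int] = {}
    for t in terms:
        g = group_map.get(t, "other")
        counts[g] = counts.get(g, 0) + 1
    total = len(terms)
    return {g: c / total for g, c in sorted(counts.items())}


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: term <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
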