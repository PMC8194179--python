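"""Hand-built toy DE tables exercising the integration filter logic.

These synthetic stand-in tables are small enough to verify by hand and are
constructed so the integration operations reproduce the *structure* of the
study's published gene lists: the two-dataset concordant overlap yields
3 up-regulated and 4 down-regulated genes, and the five-dataset candidate
Venn yields 4 genes up-in-invasion/down-on-inhibition and 9 the other way.
Gene names follow the published lists where they are printed; the deeper
members of the nine-gene list are plausible keratinization/differentiation
genes and are synthetic placements, not data.
"""

from __future__ import annotations

import pandas as pd

from .integration import DETable

__all__ = [
    "two_dataset_tables",
    "five_dataset_tables",
    "UP_IN_BOTH",
    "DOWN_IN_BOTH",
    "VENN_UP",
    "VENN_DOWN",
]

#: Expected two-dataset concordant overlap membership.
UP_IN_BOTH = ("LAPTM5", "LCK", "STAT5B")
DOWN_IN_BOTH = ("GFOD1", "MXD1", "SERPINB2", "TGFA")

#: Expected candidate Venn membership (up list printed; down list planted).
VENN_UP = ("ETV4", "KIF21B", "LAPTM5", "LPXN")
VENN_DOWN = ("IVL", "KRT14", "KRT17", "SERPINB2", "SPRR1B", "SPRR2A",
             "SPRR2D", "SPRR2F", "TGM1")

_SIG, _NS = 0.001, 0.5  # representative significant / non-significant FDR


def _table(dataset_id: str, rows: list[tuple[str, float, float, float]]) -> DETable:
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "fdr", "log2cpm"])
    df["p_value"] = df["fdr"] / 2.0
    return DETable(dataset_id=dataset_id,
                   data=df[["gene", "log2fc", "p_value", "fdr", "log2cpm"]])


def two_dataset_tables() -> tuple[DETable, DETable]:
    """Metastasis (m) and invasive-clone (c) tables for the concordant
    overlap: 3 genes pass up, 4 pass down, and decoys fail exactly one
    filter each (discordant sign, single-dataset significance, low CPM)."""
    m_rows = [
        # concordant up, abundant, significant in both
        ("LAPTM5",    1.8, _SIG, 5.0),
        ("LCK",       2.2, _SIG, 4.0),
        ("STAT5B",    0.9, _SIG, 6.0),
        # concordant down
        ("SERPINB2", -2.5, _SIG, 5.5),
        ("GFOD1",    -0.8, _SIG, 4.2),
        ("TGFA",     -0.7, _SIG, 5.1),
        ("MXD1",     -0.6, _SIG, 4.8),
        # discordant sign
        ("ETV4",      1.4, _SIG, 5.0),
        # significant here only
        ("KRT14",    -1.9, _SIG, 6.0),
        # concordant up but lowly expressed
        ("ANXA1",     1.1, _SIG, 1.5),
    ]
    c_rows = [
        ("LAPTM5",    2.6, _SIG, 4.8),
        ("LCK",       3.0, _SIG, 4.5),
        ("STAT5B",    0.7, _SIG, 5.5),
        ("SERPINB2", -1.9, _SIG, 5.0),
        ("GFOD1",    -1.1, _SIG, 4.0),
        ("TGFA",     -0.9, _SIG, 4.9),
        ("MXD1",     -0.5, _SIG, 4.4),
        ("ETV4",     -1.2, _SIG, 5.2),   # flips sign vs m
        ("KRT14",    -1.5, _NS,  6.1),   # not significant here
        ("ANXA1",     1.3, _SIG, 1.8),   # still lowly expressed
    ]
    return _table("m", m_rows), _table("c", c_rows)


def five_dataset_tables() -> list[DETable]:
    """All five contrasts for the candidate Venn.

    Four genes are significantly up in m or c and significantly down in at
    least one inhibition contrast; nine genes show the mirror pattern;
    decoys are significant on one side only or not at all.
    """
    # gene -> {contrast: (log2fc, fdr)}; missing contrasts are filled
    # non-significant with a small same-sign residual fold change.
    patterns: dict[str, dict[str, tuple[float, float]]] = {
        # --- up in invasion, down on inhibition (the 4 candidates)
        "LAPTM5": {"m": (1.8, _SIG), "c": (2.6, _SIG), "s": (-1.5, _SIG),
                   "l": (-0.9, _SIG), "d": (-1.1, _SIG)},
        "LPXN":   {"m": (0.6, _NS), "c": (1.4, _SIG), "s": (-0.4, _NS),
                   "l": (-1.2, _SIG), "d": (-0.5, _NS)},
        "ETV4":   {"m": (0.3, _NS), "c": (1.1, _SIG), "s": (-0.2, _NS),
                   "l": (-0.3, _NS), "d": (-1.0, _SIG)},
        "KIF21B": {"m": (1.2, _SIG), "c": (0.5, _NS), "s": (-0.8, _SIG),
                   "l": (-0.2, _NS), "d": (-0.4, _NS)},
        # --- down in invasion, up on inhibition (the 9 candidates)
        "SERPINB2": {"m": (-2.5, _SIG), "c": (-1.9, _SIG), "s": (1.0, _SIG),
                     "l": (0.8, _SIG), "d": (0.6, _NS)},
        "TGM1":   {"m": (-1.1, _SIG), "c": (-0.4, _NS), "s": (0.9, _SIG),
                   "l": (0.7, _SIG), "d": (0.8, _SIG)},
        "KRT14":  {"m": (-1.9, _SIG), "c": (-0.6, _NS), "s": (1.4, _SIG),
                   "l": (0.5, _NS), "d": (1.0, _SIG)},
        "KRT17":  {"m": (-0.8, _NS), "c": (-1.2, _SIG), "s": (0.7, _SIG),
                   "l": (0.9, _SIG), "d": (0.3, _NS)},
        "SPRR2A": {"m": (-0.5, _NS), "c": (-1.6, _SIG), "s": (1.8, _SIG),
                   "l": (1.1, _SIG), "d": (1.3, _SIG)},
        "SPRR2D": {"m": (-1.3, _SIG), "c": (-0.3, _NS), "s": (1.2, _SIG),
                   "l": (0.6, _NS), "d": (0.9, _SIG)},
        "SPRR2F": {"m": (-0.9, _SIG), "c": (-0.7, _NS), "s": (0.4, _NS),
                   "l": (1.0, _SIG), "d": (0.5, _NS)},
        "SPRR1B": {"m": (-0.4, _NS), "c": (-1.0, _SIG), "s": (0.8, _SIG),
                   "l": (0.4, _NS), "d": (0.7, _SIG)},
        "IVL":    {"m": (-0.7, _SIG), "c": (-0.5, _NS), "s": (0.5, _NS),
                   "l": (0.8, _SIG), "d": (1.1, _SIG)},
        # --- decoys
        # up in invasion but never significantly down on inhibition
        "STAT5B": {"m": (0.9, _SIG), "c": (0.7, _SIG), "s": (-0.2, _NS),
                   "l": (-0.1, _NS), "d": (-0.3, _NS)},
        # down on inhibition only
        "GFOD1":  {"m": (-0.3, _NS), "c": (-0.2, _NS), "s": (-0.9, _SIG),
                   "l": (-0.7, _SIG), "d": (-0.5, _SIG)},
        # nothing significant anywhere
        "ACTB":   {"m": (0.1, _NS), "c": (-0.1, _NS), "s": (0.05, _NS),
                   "l": (-0.02, _NS), "d": (0.03, _NS)},
    }
    tables = []
    for ds in ("m", "c", "s", "l", "d"):
        rows = [(gene, fc_fdr[ds][0], fc_fdr[ds][1], 5.0)
                for gene, fc_fdr in patterns.items()]
        tables.append(_table(ds, rows))
    return tables
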