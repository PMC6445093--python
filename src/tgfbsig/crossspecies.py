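"""Cross-species refinement of the human progression-protein set.

The human up/down progression proteins are intersected with mouse
prediagnostic risers (fold change F20 = prediagnostic-2 / baseline in
the fast-tumor group, strictly greater than 1.3), filtered for
tumor-intrinsic expression (detection in a TNBC cell-line spectral-count
panel), and compared with the metastatic-vs-non-metastatic secretome
(BPLER/HMLER conditioned-media ratios, >= 1.5 up and <= 0.67 down in
both pairs, boundaries inclusive).  The refined signature is the set of
proteins concordantly up in the human metastatic group and the mouse
fast group that survive the tumor-intrinsic filter.

Human-mouse matching is by case-insensitive symbol equality; no
orthology tables are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: signature proteins with literature-reported TGFB regulation (static
#: metadata carried for reporting, not computed)
KNOWN_TGFB_REGULATED = frozenset({"ACTA1", "B2M", "FGA", "FGFR1", "SERPINA3"})


def mouse_fold_changes(series: pd.DataFrame) -> pd.DataFrame:
    """F10/F20 (fast) and S10/S20 (slow) prediagnostic-to-baseline ratios.

    ``series`` has columns ``protein_symbol, group, baseline, prediag1,
    prediag2``.  Proteins with a non-positive baseline are skipped with
    a log message.
    """
    required = {"protein_symbol", "group", "baseline", "prediag1", "prediag2"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"mouse series missing columns: {sorted(missing)}")
    bad = series["baseline"] <= 0
    if bad.any():
        logger.warning("skipping %d mouse rows with non-positive baseline",
                       int(bad.sum()))
        series = series[~bad]
    out = {}
    for group, prefix in (("fast", "F"), ("slow", "S")):
        sub = series[series["group"] == group].set_index("protein_symbol")
        out[f"{prefix}10"] = sub["prediag1"] / sub["baseline"]
        out[f"{prefix}20"] = sub["prediag2"] / sub["baseline"]
    return pd.DataFrame(out)


def mouse_progression_proteins(series: pd.DataFrame,
                               f20_cutoff: float = 1.3) -> set[str]:
    """Proteins whose fast-group F20 strictly exceeds the cutoff."""
    fc = mouse_fold_changes(series)
    return set(fc.index[fc["F20"] > f20_cutoff])


def intersect_species(human_up: Iterable[str], human_down: Iterable[str],
                      mouse_set: Iterable[str],
                      mouse_fc: pd.DataFrame | None = None) -> pd.DataFrame:
    """Common human/mouse progression proteins with direction annotation.

    Matching is case-insensitive on symbols; the returned frame is
    indexed by the human-cased symbol with the human direction and, when
    ``mouse_fc`` is supplied, the F10/F20/S10/S20 columns.
    """
    up = {s.upper(): s for s in human_up}
    down = {s.upper(): s for s in human_down}
    overlap_keys = (set(up) | set(down)) & {s.upper() for s in mouse_set}
    rows = []
    for key in sorted(overlap_keys):
        symbol = up.get(key, down.get(key))
        rows.append({"protein_symbol": symbol,
                     "human_direction": "up" if key in up else "down"})
    out = pd.DataFrame(rows, columns=["protein_symbol", "human_direction"])
    out = out.set_index("protein_symbol")
    if mouse_fc is not None and len(out):
        mfc = mouse_fc.copy()
        mfc.index = mfc.index.str.upper()
        for col in mfc.columns:
            out[col] = [mfc[col].get(s.upper(), np.nan) for s in out.index]
    return out


def tumor_intrinsic_filter(symbols: Iterable[str], panel: pd.DataFrame,
                           min_lines: int = 1, min_count: int = 1
                           ) -> tuple[set[str], set[str]]:
    """Keep symbols detected in the cell-line panel; report the removed.

    ``panel`` is protein x cell-line spectral counts (any compartment
    already concatenated column-wise).  Detection means count >=
    ``min_count`` in at least ``min_lines`` lines.
    """
    if panel.empty:
        raise ValueError("cell-line panel is empty")
    detected_rows = (panel >= min_count).sum(axis=1) >= min_lines
    detected = set(panel.index[detected_rows])
    symbols = set(symbols)
    retained = symbols & detected
    removed = symbols - retained
    if removed:
        logger.info("tumor-intrinsic filter removed %d proteins: %s",
                    len(removed), sorted(removed))
    return retained, removed


def secretome_differential(pair_ratios: pd.DataFrame, up_cutoff: float = 1.5,
                           down_cutoff: float = 0.67
                           ) -> tuple[set[str], set[str]]:
    """Commonly regulated conditioned-media proteins across both pairs.

    ``pair_ratios`` is protein x 2 metastatic/non-metastatic ratio
    columns (BPLER/HMLER).  Up requires ratio >= ``up_cutoff`` in both
    pairs, down requires <= ``down_cutoff`` in both; boundaries are
    inclusive.  Proteins with a missing ratio in either pair are
    excluded from both sets.
    """
    if pair_ratios.shape[1] != 2:
        raise ValueError("expected exactly 2 pair-ratio columns")
    complete = pair_ratios.notna().all(axis=1)
    n_missing = int((~complete).sum())
    if n_missing:
        logger.info("excluded %d proteins missing in one pair", n_missing)
    sub = pair_ratios[complete]
    up = set(sub.index[(sub >= up_cutoff).all(axis=1)])
    down = set(sub.index[(sub <= down_cutoff).all(axis=1)])
    return up, down


def refine_signature(common: pd.DataFrame, tumor_intrinsic: Iterable[str],
                     required_direction: str = "up") -> list[str]:
    """Ordered signature genes: concordantly up in both species and
    tumor-intrinsic.

    ``common`` is the output of :func:`intersect_species` (membership
    there already implies the mouse F20 criterion).  Returns symbols
    alphabetically; an empty result is a warning, not an error.
    """
    tumor_intrinsic = set(tumor_intrinsic)
    hits = [s for s in common.index
            if common.loc[s, "human_direction"] == required_direction
            and s in tumor_intrinsic]
    if not hits:
        logger.warning("refined signature is empty")
    return sorted(hits)


@dataclass
class IntegrationResult:
    """Full cross-species refinement with provenance."""

    mouse_fc: pd.DataFrame
    mouse_set: set[str]
    common: pd.DataFrame
    tumor_intrinsic: set[str]
    removed_not_in_celllines: set[str]
    secretome_up: set[str]
    secretome_down: set[str]
    signature: list[str]

    def provenance_table(self) -> pd.DataFrame:
        """One row per common protein with every filter's evidence."""
        out = self.common.copy()
        out["in_cell_lines"] = [s in self.tumor_intrinsic for s in out.index]
        out["secretome_up"] = [s in self.secretome_up for s in out.index]
        out["secretome_down"] = [s in self.secretome_down for s in out.index]
        out["in_signature"] = [s in self.signature for s in out.index]
        out["known_tgfb_regulated"] = [s.upper() in KNOWN_TGFB_REGULATED
                                       for s in out.index]
        return out


def integrate(human_up: Iterable[str], human_down: Iterable[str],
              mouse_series: pd.DataFrame, panel: pd.DataFrame,
              secretome_ratios: pd.DataFrame | None = None,
              f20_cutoff: float = 1.3, min_lines: int = 1, min_count: int = 1,
              up_cutoff: float = 1.5, down_cutoff: float = 0.67
              ) -> IntegrationResult:
    """Run the whole cross-species refinement chain."""
    mouse_fc = mouse_fold_changes(mouse_series)
    mouse_set = set(mouse_fc.index[mouse_fc["F20"] > f20_cutoff])
    common = intersect_species(human_up, human_down, mouse_set, mouse_fc=mouse_fc)
    retained, removed = tumor_intrinsic_filter(common.index, panel,
                                               min_lines=min_lines,
                                               min_count=min_count)
    if secretome_ratios is not None:
        sec_up, sec_down = secretome_differential(secretome_ratios,
                                                  up_cutoff=up_cutoff,
                                                  down_cutoff=down_cutoff)
    else:
        sec_up, sec_down = set(), set()
    signature = refine_signature(common, retained)
    return IntegrationResult(mouse_fc=mouse_fc, mouse_set=mouse_set, common=common,
                             tumor_intrinsic=retained,
                             removed_not_in_celllines=removed,
                             secretome_up=sec_up, secretome_down=sec_down,
                             signature=signature)
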