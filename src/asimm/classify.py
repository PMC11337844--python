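"""Resident / immigrant population classification and persistence analysis.

Every genus detected at the end of Phase 2 in at least one reactor of a
set is assigned exactly one of four categories by comparing the three
feed conditions (27 reactors: 9 fed synthetic wastewater only, 9 fed
synthetic wastewater + live influent solids, 9 fed synthetic wastewater
+ autoclaved influent solids):

* ``core_resident`` -- detected in >= 80% of all 27 reactors with a
  mean relative abundance >= 0.1%;
* ``non_core_resident`` -- detected in at least one reactor *without*
  immigration (synthetic-feed-only) but failing the core criteria;
* ``growing_immigrant`` -- absent from every synthetic-feed-only
  reactor and more abundant in the live-solids reactors than in the
  autoclaved (sterile) controls: present because of immigration and
  actively growing;
* ``residual_immigrant`` -- absent from synthetic-feed-only reactors
  and at equal-or-lower abundance than the sterile control: residual
  DNA / carried-over biomass, not growing.

The module also summarises read fractions per category across the
set's reactors and runs the Phase-3 persistence odds-ratio analysis:
do growing immigrants with a positive Phase-2 net growth rate persist
after immigration stops?
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import FLAG_ND_INFLUENT

__all__ = [
    "CATEGORIES",
    "min_occupancy_count",
    "classify_genera",
    "category_read_summary",
    "persistence_analysis",
    "PersistenceResult",
    "write_classification",
    "write_summary",
]

CORE = "core_resident"
NON_CORE = "non_core_resident"
GROWING = "growing_immigrant"
RESIDUAL = "residual_immigrant"
CATEGORIES = (CORE, NON_CORE, GROWING, RESIDUAL)

RESIDENT_CATEGORIES = (CORE, NON_CORE)
IMMIGRANT_CATEGORIES = (GROWING, RESIDUAL)


def min_occupancy_count(n_reactors: int, threshold: float) -> int:
    """Smallest k with k/n_reactors >= threshold, i.e. ceil(threshold*n).

    With the study's 27 reactors and an 80% occupancy requirement the
    cutoff is 22 reactors.
    """
    if n_reactors < 1:
        raise ValueError("n_reactors must be >= 1")
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    # guard against float artefacts like 0.8*10 -> 8.000000000000002
    return int(math.ceil(threshold * n_reactors - 1e-9))


def _set_samples(meta: pd.DataFrame, set_id: str, phase: str) -> pd.DataFrame:
    sel = meta[
        (meta["set"] == set_id)
        & (meta["phase"] == phase)
        & (meta["feed"].isin(("syntho_only", "active_solids", "autoclaved_solids")))
    ]
    missing = {"syntho_only", "active_solids", "autoclaved_solids"} - set(sel["feed"])
    if missing:
        raise ValueError(
            f"set {set_id!r} at {phase} is missing feed condition(s): {sorted(missing)}"
        )
    return sel


def classify_genera(
    genus_relab: pd.DataFrame,
    meta: pd.DataFrame,
    set_id: str,
    occupancy_threshold: float = 0.8,
    abundance_threshold: float = 0.001,
    residual_ratio: float = 1.0,
    expected_reactors: int = 27,
    phase: str = "P2F",
) -> pd.DataFrame:
    """Classify every detected genus of one reactor set.

    Parameters
    ----------
    genus_relab:
        Genus x sample relative-abundance table (fractions).
    meta:
        Sample metadata indexed by sample id.
    set_id:
        Reactor set to classify (all three feed conditions at the end
        of ``phase`` must be present).
    occupancy_threshold, abundance_threshold:
        Core-resident criteria: detection in at least
        ``ceil(occupancy_threshold * n_reactors)`` reactors and mean
        relative abundance >= ``abundance_threshold`` over all the
        set's reactors.
    residual_ratio:
        A genus absent from synthetic-feed-only reactors is a growing
        immigrant when ``mean(active) > residual_ratio * mean(autoclaved)``,
        else a residual immigrant.  The default 1.0 is a strict
        equal-abundance comparison; raise it to buffer sampling noise.

    Returns
    -------
    DataFrame indexed by genus with columns ``category``, ``occupancy``
    (reactors detected / reactors total), ``mean_abundance`` and
    ``evidence`` (active/control abundance ratio, immigrants only).
    "Detected" means a non-zero value, i.e. >= 1 read after
    rarefaction.
    """
    sel = _set_samples(meta, set_id, phase)
    reactor_ids = [s for s in sel.index if s in genus_relab.columns]
    absent = [s for s in sel.index if s not in genus_relab.columns]
    if absent:
        raise ValueError(f"metadata reactors missing from table: {absent}")
    n = len(reactor_ids)
    if n != expected_reactors:
        warnings.warn(
            f"set {set_id!r} has {n} reactors (expected {expected_reactors}); "
            f"occupancy cutoff recomputed as {min_occupancy_count(n, occupancy_threshold)}",
            UserWarning,
            stacklevel=2,
        )
    cutoff = min_occupancy_count(n, occupancy_threshold)

    sub = genus_relab.loc[:, reactor_ids]
    feeds = sel.loc[reactor_ids, "feed"]
    syn_cols = feeds.index[feeds == "syntho_only"]
    act_cols = feeds.index[feeds == "active_solids"]
    aut_cols = feeds.index[feeds == "autoclaved_solids"]

    detected_any = (sub > 0).any(axis=1)
    sub = sub.loc[detected_any]

    occ_count = (sub > 0).sum(axis=1)
    mean_ab = sub.mean(axis=1)
    in_syntho = (sub.loc[:, syn_cols] > 0).any(axis=1)
    mean_act = sub.loc[:, act_cols].mean(axis=1)
    mean_aut = sub.loc[:, aut_cols].mean(axis=1)

    is_core = (occ_count >= cutoff) & (mean_ab >= abundance_threshold)
    is_growing = mean_act > residual_ratio * mean_aut

    category = pd.Series(RESIDUAL, index=sub.index, dtype=object)
    category[~in_syntho & is_growing] = GROWING
    category[in_syntho & ~is_core] = NON_CORE
    category[is_core] = CORE

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_act / mean_aut
    evidence = pd.Series(np.nan, index=sub.index)
    imm = category.isin(IMMIGRANT_CATEGORIES)
    evidence[imm] = ratio[imm]

    return pd.DataFrame(
        {
            "category": category,
            "occupancy": occ_count / n,
            "mean_abundance": mean_ab,
            "evidence": evidence,
        },
        index=pd.Index(sub.index, name="genus"),
    )


def category_read_summary(
    genus_relab: pd.DataFrame,
    classification: pd.DataFrame,
    meta: pd.DataFrame,
    set_id: str,
    phase: str = "P2F",
) -> pd.DataFrame:
    """Per-category genus counts and read percentages (mean +/- SD).

    The percentage of a reactor's reads belonging to a category is the
    summed relative abundance of the category's genera in that reactor,
    times 100.  Resident categories are averaged across all the set's
    reactors; immigrant categories across the active-solids reactors
    only (immigrant genera are absent from the others by definition).
    SD is the sample standard deviation (ddof=1) across reactors.
    """
    missing = [g for g in genus_relab.index if g not in classification.index]
    covered = classification.index.intersection(genus_relab.index)
    sel = _set_samples(meta, set_id, phase)
    reactor_ids = [s for s in sel.index if s in genus_relab.columns]
    act_ids = [s for s in reactor_ids if sel.loc[s, "feed"] == "active_solids"]

    rows = []
    for cat in CATEGORIES:
        genera = classification.index[classification["category"] == cat]
        genera = genera.intersection(genus_relab.index)
        cols = act_ids if cat in IMMIGRANT_CATEGORIES else reactor_ids
        sums = genus_relab.loc[genera, cols].sum(axis=0) * 100.0
        rows.append(
            {
                "category": cat,
                "n_genera": len(genera),
                "pct_reads_mean": float(sums.mean()) if len(cols) else np.nan,
                "pct_reads_sd": float(sums.std(ddof=1)) if len(cols) > 1 else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("category")
    out.attrs["unclassified_genera"] = list(missing)
    return out


@dataclass
class PersistenceResult:
    """2x2 persistence table and its odds ratio.

    ``table`` rows are the Phase-2 net-growth sign (positive, negative),
    columns the Phase-3 fate (persisting, lost).  ``odds_ratio`` is
    (a/b)/(c/d); when any cell is zero the Haldane-Anscombe correction
    (+0.5 on every cell) is applied first.  ``pct_persisters_positive``
    is the share of persisting genera that had a positive Phase-2 net
    growth rate.
    """

    table: np.ndarray
    odds_ratio: float
    pct_persisters_positive: float
    n_excluded: int = 0
    haldane_corrected: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.table,
            index=pd.Index(["mu_net_positive", "mu_net_negative"], name="phase2_sign"),
            columns=["persisting", "lost"],
        )


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """(a/b)/(c/d) with Haldane-Anscombe +0.5 on all cells iff any is zero."""
    cells = [a, b, c, d]
    if min(cells) < 0:
        raise ValueError("contingency cells must be non-negative")
    corrected = 0 in cells
    if corrected:
        a, b, c, d = (x + 0.5 for x in cells)
    return (a / b) / (c / d), corrected


def persistence_analysis(
    classification_p2: pd.DataFrame,
    growth_p2: pd.DataFrame,
    genus_relab_p3: pd.DataFrame,
    meta: pd.DataFrame,
    set_id: str,
) -> PersistenceResult:
    """Odds-ratio test: does a positive Phase-2 net growth rate predict
    persistence through Phase 3 once immigration stops?

    Operates on the set's growing immigrants.  A genus *persists* when
    it is detected in at least one active-solids reactor at the end of
    Phase 3.  Genera whose net growth rate is unavailable (not detected
    in the influent) are excluded and counted in ``n_excluded``.
    """
    growing = classification_p2.index[classification_p2["category"] == GROWING]
    if len(growing) == 0:
        raise ValueError("nothing to analyze: no growing immigrants in Phase-2 classification")
    missing = [g for g in growing if g not in growth_p2.index]
    if missing:
        raise ValueError(f"growth records missing for growing immigrants: {missing}")

    sel = meta[
        (meta["set"] == set_id)
        & (meta["phase"] == "P3F")
        & (meta["feed"] == "active_solids")
    ]
    p3_cols = [s for s in sel.index if s in genus_relab_p3.columns]
    if not p3_cols:
        raise ValueError(f"no Phase-3 active-solids samples for set {set_id!r}")

    records = growth_p2.loc[growing]
    usable = records[records["flag"] != FLAG_ND_INFLUENT].dropna(subset=["mu_net"])
    n_excluded = len(growing) - len(usable)

    persisting = (
        genus_relab_p3.reindex(usable.index, fill_value=0.0).loc[:, p3_cols] > 0
    ).any(axis=1)
    positive = usable["mu_net"] > 0

    a = int((positive & persisting).sum())
    b = int((positive & ~persisting).sum())
    c = int((~positive & persisting).sum())
    d = int((~positive & ~persisting).sum())
    oratio, corrected = odds_ratio_2x2(a, b, c, d)
    pct = 100.0 * a / (a + c) if (a + c) > 0 else float("nan")
    return PersistenceResult(
        table=np.array([[a, b], [c, d]], dtype=int),
        odds_ratio=oratio,
        pct_persisters_positive=pct,
        n_excluded=n_excluded,
        haldane_corrected=corrected,
    )


def write_classification(classification: pd.DataFrame, path, provenance=None) -> None:
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        for line in provenance or ():
            fh.write(f"# {line}\n")
        classification.to_csv(fh, sep="\t", index_label="genus", lineterminator="\n")


def write_summary(summary: pd.DataFrame, path, provenance=None) -> None:
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        for line in provenance or ():
            fh.write(f"# {line}\n")
        summary.to_csv(fh, sep="\t", index_label="category", lineterminator="\n")
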