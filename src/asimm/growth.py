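"""Steady-state mass-balance model of immigration and net growth.

For a completely mixed activated-sludge (AS) reactor at steady state,
the biomass of taxon *i* is maintained by two processes: growth in the
reactor and continuous immigration with the influent.  Writing theta_x
for the solids retention time (SRT), theta for the hydraulic retention
time (HRT) and b_i for the specific decay rate, the taxon-specific
growth rate is

    mu_i = (1/theta_x + b_i) * (1 - m_i)                          (growth)

where the immigration level m_i in [0, 1] is the fraction of the
taxon's AS biomass that immigrated rather than grew in situ:

    m_i = X_Bio,i,Inf / (X_Bio,i,AS * (theta/theta_x) * (1 + b_i*theta_x))

Translating biomass concentrations into the 16S relative abundances a
sequencing experiment measures (f_Inf, f_AS), with f_Capt the capture
fraction of influent biomass by the sludge, X_Tot the total solids and
gamma_DNA the DNA extraction yields of the two compartments, gives the
forward map

    f_AS = R * f_Inf / (1 - mu_net * theta_x),
    R    = (theta_x/theta) * f_Capt * (X_Tot,Inf*gamma_Inf) / (X_Tot,AS*gamma_AS)

where mu_net = mu - b is the net specific growth rate.  ``R`` is the
abundance transfer factor: the AS/influent abundance ratio of a taxon
with zero net growth.  Inverting the forward map estimates mu_net from
a pair of measured relative abundances:

    mu_net = (1/theta_x) * (1 - R * f_Inf / f_AS)

In log10-log10 space the forward map is a family of 45-degree lines;
taxa on the same line share a net growth rate, and the line through
intercept log10(R) is the zero-net-growth border: points above it grow
(mu_net > 0), points below are diluted faster than they grow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ReactorParameters",
    "DEFAULT_DECAY",
    "growth_rate_from_immigration",
    "immigration_level",
    "abundance_transfer_factor",
    "predict_as_abundance",
    "estimate_net_growth",
    "zero_growth_border",
    "growth_table",
    "write_growth_table",
    "FLAG_OK",
    "FLAG_ND_INFLUENT",
    "FLAG_ND_AS",
]

#: Default specific decay rate b_i (1/day), applied to every taxon unless
#: overridden.  Affects only m_i and mu_i, never mu_net estimated from the
#: abundance map.
DEFAULT_DECAY = 0.2

FLAG_OK = "ok"
#: taxon not detected in the influent: not immigration-sourced, mu_net
#: undefined by this model.
FLAG_ND_INFLUENT = "not_immigration_sourced"
#: taxon detected in the influent but not in the AS: below the washout
#: floor, mu_net is only bounded from above.
FLAG_ND_AS = "nd_on_as_axis"


@dataclass(frozen=True)
class ReactorParameters:
    """Operating parameters of the reactor and the two measured compartments.

    Attributes
    ----------
    srt:
        Solids retention time theta_x (days).
    hrt:
        Hydraulic retention time theta (days).
    capture_fraction:
        Fraction of influent biomass captured by the AS solids
        (f_Capt, dimensionless, in (0, 1]).
    x_tot_inf, x_tot_as:
        Total (volatile suspended) solids of influent feed and mixed
        liquor, mg-VSS/L.
    gamma_dna_inf, gamma_dna_as:
        DNA extraction yields per unit solids for the two compartments;
        only their ratio matters, so any consistent unit works.
    """

    srt: float = 5.0
    hrt: float = 1.8
    capture_fraction: float = 1.0
    x_tot_inf: float = 120.0
    x_tot_as: float = 900.0
    gamma_dna_inf: float = 1.0
    gamma_dna_as: float = 1.0

    def __post_init__(self):
        if self.srt <= 0 or self.hrt <= 0:
            raise ValueError("srt and hrt must be positive")
        if not (0 < self.capture_fraction <= 1):
            raise ValueError("capture_fraction must be in (0, 1]")
        if self.x_tot_inf <= 0 or self.x_tot_as <= 0:
            raise ValueError("solids concentrations must be positive")
        if self.gamma_dna_inf <= 0 or self.gamma_dna_as <= 0:
            raise ValueError("DNA yields must be positive")

    @classmethod
    def from_mapping(cls, cfg: Mapping[str, float]) -> "ReactorParameters":
        """Build parameters from flat config keys (srt_days, hrt_days, ...)."""
        keymap = {
            "srt_days": "srt",
            "hrt_days": "hrt",
            "capture_fraction": "capture_fraction",
            "x_tot_inf": "x_tot_inf",
            "x_tot_as": "x_tot_as",
            "gamma_dna_inf": "gamma_dna_inf",
            "gamma_dna_as": "gamma_dna_as",
        }
        kwargs = {attr: float(cfg[key]) for key, attr in keymap.items() if key in cfg}
        return cls(**kwargs)

    def replace(self, **kwargs) -> "ReactorParameters":
        return replace(self, **kwargs)


def growth_rate_from_immigration(m, params: ReactorParameters, decay: float = DEFAULT_DECAY):
    """Taxon growth rate mu_i (1/day) from its immigration level.

    ``mu = (1/theta_x + b) * (1 - m)``; at ``m=0`` the taxon sustains
    itself entirely by growth (mu = 1/theta_x + b), at ``m=1`` all its
    biomass immigrated (mu = 0).
    """
    m_arr = np.asarray(m, dtype=float)
    if np.any((m_arr < 0) | (m_arr > 1)):
        raise ValueError(f"immigration level must be in [0, 1], got {m}")
    out = (1.0 / params.srt + decay) * (1.0 - m_arr)
    return float(out) if np.isscalar(m) else out


def immigration_level(
    x_bio_inf,
    x_bio_as,
    params: ReactorParameters,
    decay: float = DEFAULT_DECAY,
):
    """Immigration level m_i from influent and AS biomass concentrations.

    ``m = X_Inf / (X_AS * (theta/theta_x) * (1 + b*theta_x))``.  Values
    above 1 indicate physically inconsistent inputs (more biomass
    arriving than present); they are clipped to 1 with a warning.
    """
    x_inf = np.asarray(x_bio_inf, dtype=float)
    x_as = np.asarray(x_bio_as, dtype=float)
    if np.any(x_as <= 0):
        raise ValueError("x_bio_as must be positive")
    m = x_inf / (x_as * (params.hrt / params.srt) * (1.0 + decay * params.srt))
    if np.any(m > 1):
        warnings.warn(
            "immigration level > 1: influent biomass exceeds steady-state "
            "supply; clipping to 1 (inconsistent input)",
            UserWarning,
            stacklevel=2,
        )
        m = np.minimum(m, 1.0)
    return float(m) if np.isscalar(x_bio_inf) and np.isscalar(x_bio_as) else m


def abundance_transfer_factor(params: ReactorParameters) -> float:
    """Abundance transfer factor R (dimensionless).

    ``R = (theta_x/theta) * f_Capt * (X_Tot,Inf*gamma_Inf) / (X_Tot,AS*gamma_AS)``:
    the expected AS/influent relative-abundance ratio of a taxon with
    zero net growth.
    """
    return (
        (params.srt / params.hrt)
        * params.capture_fraction
        * (params.x_tot_inf * params.gamma_dna_inf)
        / (params.x_tot_as * params.gamma_dna_as)
    )


def predict_as_abundance(f_inf, mu_net, params: ReactorParameters):
    """Forward map: expected AS relative abundance of an immigrating taxon.

    ``f_AS = R * f_Inf / (1 - mu_net*theta_x)``, strictly increasing in
    ``mu_net`` on its domain ``mu_net < 1/theta_x``.  At the domain
    boundary the taxon is fully self-sustaining and its AS abundance is
    decoupled from the influent, so the map is inapplicable.
    """
    mu = np.asarray(mu_net, dtype=float)
    if np.any(mu >= 1.0 / params.srt):
        raise ValueError(
            "mu_net >= 1/SRT: self-sustaining regime; abundance map inapplicable"
        )
    r = abundance_transfer_factor(params)
    out = r * np.asarray(f_inf, dtype=float) / (1.0 - mu * params.srt)
    return float(out) if np.isscalar(f_inf) and np.isscalar(mu_net) else out


def estimate_net_growth(f_inf, f_as, params: ReactorParameters):
    """Invert the forward map: mu_net (1/day) from paired abundances.

    ``mu_net = (1/theta_x) * (1 - R*f_Inf/f_AS)``.  Requires
    ``f_inf > 0`` (a taxon absent from the influent is not
    immigration-sourced and its net growth rate cannot be obtained from
    this map).  ``f_as = 0`` returns ``-inf``: the taxon is below the
    washout floor and only an upper bound exists; tabular callers
    should use :func:`growth_table`, which flags these cases instead of
    propagating infinities.
    """
    fi = np.asarray(f_inf, dtype=float)
    fa = np.asarray(f_as, dtype=float)
    if np.any(fi <= 0):
        raise ValueError(
            "f_inf must be positive: taxon not detected in the influent is "
            "not immigration-sourced"
        )
    r = abundance_transfer_factor(params)
    with np.errstate(divide="ignore"):
        out = (1.0 / params.srt) * (1.0 - r * fi / fa)
    return float(out) if np.isscalar(f_inf) and np.isscalar(f_as) else out


def zero_growth_border(params: ReactorParameters) -> float:
    """Intercept of the zero-net-growth 45-degree line in log10-log10 space.

    The border is ``log10(f_AS) = log10(R) + log10(f_Inf)``; the
    returned value is ``log10(R)``.
    """
    return math.log10(abundance_transfer_factor(params))


# ---------------------------------------------------------------------------
# per-genus estimation from tables
# ---------------------------------------------------------------------------

def growth_table(
    as_relab: pd.DataFrame,
    influent_relab: pd.DataFrame,
    meta: pd.DataFrame,
    set_id: str,
    params: ReactorParameters,
    decay: float = DEFAULT_DECAY,
    phase: str = "P2F",
) -> pd.DataFrame:
    """Estimate per-genus immigration level and net growth for one reactor set.

    ``f_AS`` is the arithmetic mean relative abundance across the set's
    active-solids reactors at the end of ``phase``; ``f_Inf`` the mean
    across the set's influent samples.  Returns one row per genus
    (union of both tables) with columns ``f_inf, f_as, m, mu, mu_net,
    flag``.  Genera absent from the influent are flagged
    ``not_immigration_sourced`` (mu_net NaN); genera present in the
    influent but ND in the AS are flagged ``nd_on_as_axis``.
    """
    active = meta[
        (meta["set"] == set_id)
        & (meta["phase"] == phase)
        & (meta["feed"] == "active_solids")
    ].index
    influent = meta[(meta["set"] == set_id) & (meta["feed"] == "influent")].index
    active = [s for s in active if s in as_relab.columns]
    influent = [s for s in influent if s in influent_relab.columns]
    if not active:
        raise ValueError(f"no active-solids samples for set {set_id!r} at {phase}")
    if not influent:
        raise ValueError(f"no influent samples for set {set_id!r}")

    genera = as_relab.index.union(influent_relab.index, sort=False)
    f_as = as_relab.loc[:, active].mean(axis=1).reindex(genera, fill_value=0.0)
    f_inf = influent_relab.loc[:, influent].mean(axis=1).reindex(genera, fill_value=0.0)

    r = abundance_transfer_factor(params)
    srt = params.srt
    mu_net = np.full(len(genera), np.nan)
    flag = np.full(len(genera), FLAG_OK, dtype=object)

    fi = f_inf.to_numpy()
    fa = f_as.to_numpy()
    nd_inf = fi <= 0
    nd_as = (~nd_inf) & (fa <= 0)
    ok = (~nd_inf) & (~nd_as)
    flag[nd_inf] = FLAG_ND_INFLUENT
    flag[nd_as] = FLAG_ND_AS
    mu_net[ok] = (1.0 / srt) * (1.0 - r * fi[ok] / fa[ok])

    # immigration level and gross growth rate from the same steady state:
    # m = (1 - mu_net*theta_x) / (1 + b*theta_x), clipped into [0, 1]
    m = np.full(len(genera), np.nan)
    m[ok] = np.clip((1.0 - mu_net[ok] * srt) / (1.0 + decay * srt), 0.0, 1.0)
    mu = np.full(len(genera), np.nan)
    mu[ok] = (1.0 / srt + decay) * (1.0 - m[ok])

    return pd.DataFrame(
        {
            "f_inf": fi,
            "f_as": fa,
            "m": m,
            "mu": mu,
            "mu_net": mu_net,
            "flag": flag,
        },
        index=pd.Index(genera, name="genus"),
    )


def write_growth_table(table: pd.DataFrame, path, provenance=None) -> None:
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        for line in provenance or ():
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index_label="genus", lineterminator="\n")
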