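"""Forward simulator of the controlled immigration experiment.

One simulated experiment is one *reactor set*: 27 reactors (3 inoculum
blocks x 3 feed conditions x 3 replicates) sampled at the end of
Phase 2, plus influent-solids samples, plus the same reactors at the
end of Phase 3 after immigration has been stopped.  The generative
model is the same steady-state mass balance the analysis inverts, so
every downstream stage (rarefaction, classification, net-growth
estimation, persistence) can be scored against ground truth without
any sequencing data.

Generative model
----------------
A taxa pool assigns each genus a compartment profile that is exactly
consistent with the abundance map ``f_AS = R * f_Inf / (1 - mu_net*theta_x)``:

* *core-pool residents* get an AS abundance from a lognormal
  rank-abundance profile (together ~75% of reads) and a net growth
  rate drawn uniform(0.3, 0.95)/SRT; their influent abundance is the
  one the map implies, ``f_Inf = f_AS (1 - mu_net*theta_x) / R``
  (core genera are routinely detected in real influent).
* *non-core-pool residents* are inoculum legacy: low abundance, absent
  from the influent, and present only sporadically -- each genus gets a
  per-reactor occurrence probability (drift between replicate
  reactors), which is what keeps abundant-but-patchy genera out of the
  core category, as in real reactor sets.
* *growing immigrants* get influent abundances from a lognormal
  profile over the influent mass left after the core share, and
  ``mu_net`` uniform(-0.5, 0.5) 1/day truncated below the washout
  balance 1/SRT; their expected AS abundance follows the forward map.  They appear in live-solids reactors at
  that level, in autoclaved controls only at the residual-DNA level,
  and never in synthetic-feed-only reactors.
* *residual immigrants* are inert DNA: both live-solids and autoclaved
  reactors carry them at the carryover level, modelled with an
  effective net rate ``mu_net_dna`` (default -0.3 1/day).

Both the influent composition vector and each reactor's expected
composition sum to one by construction, so with noise switched off the
net-growth estimator recovers the drawn rates to numerical precision.

Noise model: block-specific lognormal perturbations of core-pool
abundances (inoculum effect), per-reactor lognormal replicate noise
applied before renormalisation, multinomial read sampling at a
per-sample depth drawn uniform from [60,000, 120,000], then
rarefaction to 40,000 reads so the rarefaction stage is always
exercised.  Influent samples are technical replicates of a single
solids stock and carry multinomial noise only.

Ground-truth categories are derived by applying the classification
rules to the noise-free expected abundance matrix, so "truth" is what
the category definitions say given the true composition, and recovery
tests measure sampling noise alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify as _classify
from .growth import DEFAULT_DECAY, ReactorParameters, abundance_transfer_factor
from .io import CountTable, TaxonomyMap, rarefy

__all__ = [
    "ExperimentDesign",
    "PoolSizes",
    "generate_taxa_pool",
    "simulate_phase2_tables",
    "simulate_phase3_washout",
    "simulate_experiment",
    "Phase2Result",
    "Phase3Result",
    "SimulatedExperiment",
    "taxonomy_for",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout and sampling parameters of one simulated reactor set."""

    set_id: str = "A"
    blocks: tuple[str, ...] = ("a", "b", "c")
    n_replicates: int = 3
    n_influent_samples: int = 3
    rarefaction_depth: int = 40_000
    depth_min: int = 60_000
    depth_max: int = 120_000
    phase3_duration_srts: float = 3.0
    #: lognormal sigma (log space) of the block-specific inoculum effect
    #: on core-pool genera
    sigma_block: float = 0.5
    #: lognormal sigma of per-reactor replicate noise, all genera
    sigma_replicate: float = 0.15
    #: effective net rate of inert carried-over DNA (1/day)
    mu_net_dna: float = -0.3
    seed: int = 0

    def __post_init__(self):
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if self.depth_min < self.rarefaction_depth:
            raise ValueError("depth_min below rarefaction depth would drop all samples")
        if self.phase3_duration_srts <= 0:
            raise ValueError("phase3_duration_srts must be positive")


@dataclass(frozen=True)
class PoolSizes:
    """Genus counts per pool; defaults sized after the study's Tables."""

    n_core: int = 60
    n_noncore: int = 125
    n_growing_imm: int = 130
    n_residual_imm: int = 8


def generate_taxa_pool(
    n_core: int,
    n_noncore: int,
    n_growing_imm: int,
    n_residual_imm: int,
    params: ReactorParameters,
    seed: int,
    core_as_total: float = 0.66,
    residual_inf_fraction: float = 0.1,
    sigma_abundance: float = 1.0,
    decay: float = DEFAULT_DECAY,
    mu_net_dna: float = -0.3,
    mu_net_core: tuple[float, float] = (0.3, 0.95),
    mu_net_growing: tuple[float, float] = (-0.5, 0.5),
    mu_net_margin: float = 0.95,
    noncore_occupancy: tuple[float, float] = (0.2, 0.85),
) -> pd.DataFrame:
    """Draw a ground-truth taxa pool.

    Returns a DataFrame indexed by genus with columns:

    ``pool``
        which prior the genus was drawn from (core / noncore /
        growing / residual);
    ``category``
        true category implied by the pool-level expectations (may be
        refined by :func:`simulate_phase2_tables` once block effects
        are drawn);
    ``mu_net``, ``decay``
        net growth rate (1/day; NaN where the concept does not apply)
        and decay rate;
    ``f_inf``
        true influent relative abundance (0 for residents absent from
        the influent);
    ``as_abundance``
        expected relative abundance in live-solids reactors;
    ``ctrl_abundance``
        expected relative abundance in autoclaved controls;
    ``occupancy_prob``
        per-reactor occurrence probability (1 for everything except
        non-core-pool residents, whose patchy occurrence across
        replicate reactors is drawn uniform from
        ``noncore_occupancy``);
    ``yield_``, ``substrate_inf``
        biomass yield Y_i (normalised to 1) and the substrate
        concentration Y_i*S_i,Inf consistent with the drawn
        immigration level, for taxa where both are defined.

    ``mu_net_core`` is in units of 1/SRT (core residents sit between
    30% and 95% of the washout-balance rate).  ``mu_net_growing`` is in
    1/day, truncated above at ``mu_net_margin/SRT``: immigrant rates
    span strongly negative (washout-bound taxa) to positive, but the
    forward map diverges at 1/SRT so the draw keeps a safety margin
    below it.  Deterministic for a given ``seed``.
    """
    for name, v in (("n_core", n_core), ("n_noncore", n_noncore),
                    ("n_growing_imm", n_growing_imm), ("n_residual_imm", n_residual_imm)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    srt = params.srt
    r = abundance_transfer_factor(params)

    def _profile(n: int, total: float) -> np.ndarray:
        if n == 0:
            return np.zeros(0)
        w = rng.lognormal(0.0, sigma_abundance, n)
        return total * w / w.sum()

    # core residents: AS abundance drawn, influent abundance implied
    core_as = _profile(n_core, core_as_total)
    mu_core = rng.uniform(*mu_net_core, n_core) / srt
    core_inf = core_as * (1.0 - mu_core * srt) / r

    inf_left = 1.0 - core_inf.sum()
    if inf_left <= 0.02:
        raise ValueError(
            "core residents exhaust the influent; lower core_as_total or "
            "raise x_tot_as (transfer factor too large)"
        )

    # immigrants: influent abundance drawn, AS abundance implied
    grow_inf = _profile(n_growing_imm, inf_left * (1.0 - residual_inf_fraction))
    lo, hi = mu_net_growing
    mu_grow = rng.uniform(lo, min(hi, mu_net_margin / srt), n_growing_imm)
    grow_as = r * grow_inf / (1.0 - mu_grow * srt)
    grow_ctrl = r * grow_inf / (1.0 - mu_net_dna * srt)

    resid_inf = _profile(n_residual_imm, inf_left * residual_inf_fraction)
    resid_as = r * resid_inf / (1.0 - mu_net_dna * srt)

    used_core = core_as_total if n_core else 0.0
    noncore_total = 1.0 - used_core - grow_as.sum() - resid_as.sum()
    if n_noncore == 0:
        # reduced pools: reactor compositions are renormalised per
        # column downstream, so an AS budget that does not reach 1 only
        # rescales every genus of a reactor jointly
        noncore_total = 0.0
    elif noncore_total <= 0:
        raise ValueError(
            "immigrant AS share exceeds the non-core budget; "
            "reduce influent load or immigrant growth rates"
        )
    noncore_as = _profile(n_noncore, noncore_total)
    occ_nc = rng.uniform(*noncore_occupancy, n_noncore)
    if n_noncore:
        # as_abundance is the conditional-on-present level; scale so the
        # expected realised non-core mass per reactor meets the budget
        noncore_as = noncore_as / occ_nc.mean()

    def _names(prefix: str, n: int) -> list[str]:
        return [f"{prefix}_{i + 1:03d}" for i in range(n)]

    genus = (
        _names("Core", n_core)
        + _names("NC", n_noncore)
        + _names("Imm", n_growing_imm)
        + _names("Rdna", n_residual_imm)
    )
    pool = (
        ["core"] * n_core + ["noncore"] * n_noncore
        + ["growing"] * n_growing_imm + ["residual"] * n_residual_imm
    )
    f_inf = np.concatenate([core_inf, np.zeros(n_noncore), grow_inf, resid_inf])
    as_ab = np.concatenate([core_as, noncore_as, grow_as, resid_as])
    ctrl_ab = np.concatenate([core_as, noncore_as, grow_ctrl, resid_as])
    mu_net = np.concatenate(
        [mu_core, np.full(n_noncore, np.nan), mu_grow, np.full(n_residual_imm, np.nan)]
    )

    occ_prob = np.concatenate(
        [np.ones(n_core), occ_nc, np.ones(n_growing_imm + n_residual_imm)]
    )

    truth = pd.DataFrame(
        {
            "pool": pool,
            "mu_net": mu_net,
            "decay": decay,
            "f_inf": f_inf,
            "as_abundance": as_ab,
            "ctrl_abundance": ctrl_ab,
            "occupancy_prob": occ_prob,
        },
        index=pd.Index(genus, name="genus"),
    )

    # categories implied by the pool-level expectations (residents need
    # both abundance and occupancy; immigrants grow iff above carryover)
    category = np.where(
        np.isin(pool, ["core", "noncore"]),
        np.where((as_ab >= 0.001) & (occ_prob >= 0.8), _classify.CORE, _classify.NON_CORE),
        np.where(
            np.array(pool) == "growing",
            np.where(as_ab > ctrl_ab, _classify.GROWING, _classify.RESIDUAL),
            _classify.RESIDUAL,
        ),
    )
    truth["category"] = category

    # Y_i and S_i,Inf consistent with the immigration level:
    # m = (1 - mu_net*srt)/(1 + b*srt), Y*S = X_Bio,Inf * (1-m)/m
    m = (1.0 - truth["mu_net"] * srt) / (1.0 + decay * srt)
    x_bio_inf = truth["f_inf"] * params.x_tot_inf
    with np.errstate(divide="ignore", invalid="ignore"):
        ys = x_bio_inf * (1.0 - m) / m
    defined = (truth["f_inf"] > 0) & truth["mu_net"].notna()
    truth["yield_"] = np.where(defined, 1.0, np.nan)
    truth["substrate_inf"] = np.where(defined, ys, np.nan)
    return truth


# ---------------------------------------------------------------------------
# phase 2
# ---------------------------------------------------------------------------

@dataclass
class Phase2Result:
    """Influent and reactor count tables with their generative state."""

    influent: CountTable
    reactors: CountTable
    metadata: pd.DataFrame
    #: noise-free expected relative abundance per reactor (genera x reactors)
    expected: pd.DataFrame
    #: truth with categories re-derived from ``expected``
    truth: pd.DataFrame

    def __iter__(self):  # allows influent, reactors, meta = result
        return iter((self.influent, self.reactors, self.metadata))


def _reactor_layout(design: ExperimentDesign) -> pd.DataFrame:
    codes = {"syntho_only": "syn", "active_solids": "act", "autoclaved_solids": "aut"}
    rows = []
    for block in design.blocks:
        for feed, code in codes.items():
            for rep in range(1, design.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{design.set_id}-{block}{rep}-{code}",
                        "set": design.set_id,
                        "block": block,
                        "feed": feed,
                        "phase": "P2F",
                        "replicate": rep,
                    }
                )
    for k in range(1, design.n_influent_samples + 1):
        rows.append(
            {
                "sample_id": f"{design.set_id}-inf-{k}",
                "set": design.set_id,
                "block": "",
                "feed": "influent",
                "phase": "P2F",
                "replicate": k,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _expected_matrix(
    truth: pd.DataFrame, design: ExperimentDesign, rng: np.random.Generator
) -> pd.DataFrame:
    """Noise-free expected relative abundances per reactor (block effects in)."""
    meta = _reactor_layout(design)
    reactors = meta[meta["feed"] != "influent"]
    pool = truth["pool"].to_numpy()
    is_core_pool = pool == "core"
    # mean-one lognormal factors so the inoculum effect perturbs core
    # composition without systematically inflating the core share
    sb = design.sigma_block
    block_factor = {
        b: np.where(is_core_pool, rng.lognormal(-0.5 * sb**2, sb, len(truth)), 1.0)
        for b in design.blocks
    }
    occ_prob = truth["occupancy_prob"].to_numpy()
    cols = {}
    for rid, row in reactors.iterrows():
        present = rng.random(len(truth)) < occ_prob
        w = np.where((pool == "noncore") & present, truth["as_abundance"], 0.0)
        w = w + np.where(is_core_pool, truth["as_abundance"] * block_factor[row["block"]], 0.0)
        if row["feed"] == "active_solids":
            w = w + np.where(np.isin(pool, ["growing", "residual"]), truth["as_abundance"], 0.0)
        elif row["feed"] == "autoclaved_solids":
            w = w + np.where(np.isin(pool, ["growing", "residual"]), truth["ctrl_abundance"], 0.0)
        cols[rid] = w / w.sum()
    return pd.DataFrame(cols, index=truth.index)


def _sample_counts(
    expected: pd.DataFrame,
    design: ExperimentDesign,
    rng: np.random.Generator,
    sigma: float,
) -> CountTable:
    cols = {}
    for sid in expected.columns:
        depth = int(rng.integers(design.depth_min, design.depth_max + 1))
        w = expected[sid].to_numpy()
        if sigma > 0:
            w = w * rng.lognormal(0.0, sigma, len(w))
        cols[sid] = rng.multinomial(depth, w / w.sum())
    return CountTable(pd.DataFrame(cols, index=expected.index))


def simulate_phase2_tables(
    truth: pd.DataFrame,
    design: ExperimentDesign,
    params: ReactorParameters,
    seed: int | None = None,
) -> Phase2Result:
    """Simulate the end-of-Phase-2 influent and reactor count tables.

    Raises if any immigrant's net growth rate reaches 1/SRT (the
    forward map is singular there).  Tables are rarefied to the design
    depth; metadata covers reactors and influent samples.
    """
    grow = truth.loc[truth["pool"] == "growing", "mu_net"]
    if (grow >= 1.0 / params.srt).any():
        raise ValueError("immigrant mu_net >= 1/SRT: forward map singular")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    meta = _reactor_layout(design)

    expected = _expected_matrix(truth, design, rng)

    # truth categories given the actual (block-perturbed) composition
    truth = truth.copy()
    cls = _classify.classify_genera(
        expected,
        meta,
        design.set_id,
        expected_reactors=len(expected.columns),
        phase="P2F",
    )
    truth.loc[cls.index, "category"] = cls["category"]

    reactors = _sample_counts(expected, design, rng, design.sigma_replicate)

    inf_ids = meta.index[meta["feed"] == "influent"]
    p_inf = truth["f_inf"].to_numpy()
    inf_cols = {}
    for sid in inf_ids:
        depth = int(rng.integers(design.depth_min, design.depth_max + 1))
        inf_cols[sid] = rng.multinomial(depth, p_inf / p_inf.sum())
    influent = CountTable(pd.DataFrame(inf_cols, index=truth.index))

    r_seed, i_seed = rng.integers(0, 2**31, size=2)
    reactors = rarefy(reactors, design.rarefaction_depth, int(r_seed))
    influent = rarefy(influent, design.rarefaction_depth, int(i_seed))
    return Phase2Result(influent=influent, reactors=reactors, metadata=meta,
                        expected=expected, truth=truth)


# ---------------------------------------------------------------------------
# phase 3
# ---------------------------------------------------------------------------

@dataclass
class Phase3Result:
    reactors: CountTable
    metadata: pd.DataFrame
    expected: pd.DataFrame


def simulate_phase3_washout(
    phase2: Phase2Result,
    truth: pd.DataFrame,
    params: ReactorParameters,
    duration_srts: float = 3.0,
    seed: int | None = None,
    design: ExperimentDesign | None = None,
) -> Phase3Result:
    """Simulate the end of Phase 3: immigration stopped, washout running.

    Over ``t = duration_srts * SRT`` days, immigration-dependent
    biomass decays as ``exp((mu_net - 1/SRT) * t)`` (growth minus
    dilution); residual DNA decays at the carryover rate
    ``exp((mu_net_dna - 1/SRT) * t)``.  Residents are at steady state
    on the synthetic feed and keep their expected abundance.  Counts
    are resampled multinomially after renormalisation, with the same
    replicate noise and depth distribution as Phase 2, then rarefied.
    """
    if duration_srts <= 0:
        raise ValueError("duration_srts must be positive")
    design = design or ExperimentDesign()
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)
    t = duration_srts * params.srt

    pool = truth["pool"].reindex(phase2.expected.index)
    factor = pd.Series(1.0, index=phase2.expected.index)
    growing = pool == "growing"
    factor[growing] = np.exp(
        (truth.loc[factor.index[growing], "mu_net"] - 1.0 / params.srt) * t
    )
    factor[pool == "residual"] = np.exp((design.mu_net_dna - 1.0 / params.srt) * t)

    w = phase2.expected.mul(factor, axis=0)
    expected3 = w / w.sum(axis=0)
    expected3.columns = [f"{c}-P3" for c in expected3.columns]

    meta2 = phase2.metadata[phase2.metadata["feed"] != "influent"]
    meta3 = meta2.copy()
    meta3.index = pd.Index([f"{c}-P3" for c in meta2.index], name="sample_id")
    meta3["phase"] = "P3F"

    reactors = _sample_counts(expected3, design, rng, design.sigma_replicate)
    reactors = rarefy(reactors, design.rarefaction_depth, int(rng.integers(0, 2**31)))
    return Phase3Result(reactors=reactors, metadata=meta3, expected=expected3)


# ---------------------------------------------------------------------------
# whole experiment
# ---------------------------------------------------------------------------

def taxonomy_for(genera: Sequence[str]) -> TaxonomyMap:
    """Synthetic identity taxonomy: each genus-level feature maps to a
    six-rank lineage ending in itself."""
    return TaxonomyMap(
        {
            g: ("Bacteria", f"P_{i % 7 + 1}", f"C_{i % 13 + 1}",
                f"O_{i % 17 + 1}", f"F_{i % 23 + 1}", g)
            for i, g in enumerate(genera)
        }
    )


@dataclass
class SimulatedExperiment:
    """Everything one simulated reactor set produces."""

    truth: pd.DataFrame
    influent: CountTable
    reactors_p2: CountTable
    reactors_p3: CountTable
    metadata: pd.DataFrame
    taxonomy: TaxonomyMap
    expected_p2: pd.DataFrame
    expected_p3: pd.DataFrame
    design: ExperimentDesign
    params: ReactorParameters
    seed: int

    def config_dict(self) -> dict:
        cfg = {f"design_{k}": v for k, v in asdict(self.design).items()}
        cfg.update({f"params_{k}": v for k, v in asdict(self.params).items()})
        cfg["seed"] = self.seed
        return cfg


def simulate_experiment(
    params: ReactorParameters | None = None,
    design: ExperimentDesign | None = None,
    sizes: PoolSizes | None = None,
    seed: int = 0,
    **pool_kwargs,
) -> SimulatedExperiment:
    """Simulate one full reactor set (pool, Phase 2, Phase 3).

    All randomness flows from ``seed`` through independent child
    streams for the pool draw, Phase-2 sampling and Phase-3 sampling.
    Extra keyword arguments are forwarded to
    :func:`generate_taxa_pool`.
    """
    params = params or ReactorParameters()
    design = design or ExperimentDesign()
    sizes = sizes or PoolSizes()
    pool_seed, p2_seed, p3_seed = (
        int(s) for s in np.random.SeedSequence(seed).generate_state(3) % (2**31)
    )
    pool_kwargs.setdefault("mu_net_dna", design.mu_net_dna)
    truth = generate_taxa_pool(
        sizes.n_core, sizes.n_noncore, sizes.n_growing_imm, sizes.n_residual_imm,
        params, pool_seed, **pool_kwargs,
    )
    p2 = simulate_phase2_tables(truth, design, params, seed=p2_seed)
    p3 = simulate_phase3_washout(
        p2, p2.truth, params,
        duration_srts=design.phase3_duration_srts, seed=p3_seed, design=design,
    )
    metadata = pd.concat([p2.metadata, p3.metadata])
    return SimulatedExperiment(
        truth=p2.truth,
        influent=p2.influent,
        reactors_p2=p2.reactors,
        reactors_p3=p3.reactors,
        metadata=metadata,
        taxonomy=taxonomy_for(list(truth.index)),
        expected_p2=p2.expected,
        expected_p3=p3.expected,
        design=design,
        params=params,
        seed=seed,
    )
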