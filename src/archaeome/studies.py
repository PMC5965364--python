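"""Synthetic study designs exercising the full workflow.

Each function builds a ground-truth-known experiment emulating one of the
study's analyses — damage-parameter recovery, authentication of
human-related vs environmental taxa against endogenous host DNA,
known-mixture profiling, and the shallow-vs-deep sequencing check — and
returns the measured quantities. They are consumed by the test suite and
the acceptance script, and are convenient entry points for exploring the
method's operating characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import damage as damage_mod
from . import preprocess, profiler, taxa
from . import simkit
from .simkit import DamageParams, SimConfig

#: damage conditions used across the synthetic studies: strongly damaged
#: ancient DNA (terminal C->T around 18-30%) over a small error floor
ANCIENT = DamageParams(delta_s=0.30, delta_d=0.01, lam=0.40, epsilon=0.001)


def standard_pack(seed: int = 0) -> simkit.ReferencePack:
    """Reference pack used by the damage-authentication studies: 12
    prokaryote taxa across the four habitats, classes spanning habitats."""
    return simkit.build_reference_pack(
        {"environmental": 6, "oral": 3, "gut_other": 2, "pathogen": 1},
        genome_length=20_000,
        markers_per_taxon=5,
        marker_length=400,
        host_genome_length=40_000,
        seed=seed,
    )


def damage_recovery(
    seeds, n_reads: int = 50_000, params: DamageParams = ANCIENT,
    pack: simkit.ReferencePack | None = None,
) -> pd.DataFrame:
    """Simulate reads at known damage parameters and refit them.

    One row per seed with the fitted (delta_s, delta_d, mean_overhang);
    alignments come from the simulator's ground truth so the experiment
    isolates the tally + estimator path.
    """
    pack = pack or standard_pack(0)
    rows = []
    for seed in seeds:
        cfg = SimConfig(
            community=[("oral_000", 1.0, params)], n_reads=n_reads, seed=seed
        )
        sample = simkit.simulate_sample(pack, cfg, f"recovery{seed}")
        prof = damage_mod.tally_misincorporations(
            simkit.truth_alignments(sample, pack), pack.genomes,
            K=25, cycles=cfg.read_length,
        )
        fit = damage_mod.fit_damage_model(prof, n_bootstrap=0)
        rows.append(
            {
                "seed": seed,
                "delta_s": fit.params.delta_s,
                "delta_d": fit.params.delta_d,
                "mean_overhang": fit.params.mean_overhang,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def _cohort_sample_config(
    pack, env_fraction: float, n_reads: int, host_fraction: float, seed: int,
    params: DamageParams,
) -> SimConfig:
    env = pack.taxa_of_habitat("environmental")
    human = [
        t for h in ("oral", "gut_other", "pathogen") for t in pack.taxa_of_habitat(h)
    ]
    microbial = 1.0 - host_fraction
    community = [(t, microbial * env_fraction / len(env), "modern") for t in env]
    community += [
        (t, microbial * (1 - env_fraction) / len(human), params) for t in human
    ]
    t0, p0, d0 = community[0]
    community[0] = (t0, p0 + (microbial - sum(p for _, p, _ in community)), d0)
    return SimConfig(
        community=community, host_fraction=host_fraction, host_damage=params,
        n_reads=n_reads, seed=seed,
    )


def authentication_cohort(
    seed: int,
    n_samples: int = 20,
    n_reads: int = 3000,
    host_fraction: float = 0.3,
    params: DamageParams = ANCIENT,
    pack: simkit.ReferencePack | None = None,
    index_cache: dict | None = None,
) -> pd.DataFrame:
    """One synthetic cohort of the authentication study.

    Human-related taxa and the host carry ancient damage; environmental
    taxa are modern. Samples span environmental fractions from 5% to 95%.
    Returns one row per sample with measured environmental fraction
    (percent), per-group damage fits and Δ (host − group) statistics.
    """
    pack = pack or standard_pack(0)
    habitat = {t: tr.habitat for t, tr in pack.traits.items() if tr.habitat}
    traits = taxa.load_trait_table(pack.trait_table())
    marker_index = profiler.MarkerIndex(
        pack.marker_sequences(),
        {
            row["marker_id"]: {k: row[k] for k in ("kingdom",) + simkit.RANKS}
            for _, row in pack.marker_taxonomy().iterrows()
        },
    )
    env_fracs = np.linspace(0.05, 0.95, n_samples)
    rows = []
    for i, env_f in enumerate(env_fracs):
        sid = f"c{seed}s{i:02d}"
        cfg = _cohort_sample_config(
            pack, float(env_f), n_reads, host_fraction, seed * 1000 + i, params
        )
        sample = simkit.simulate_sample(pack, cfg, sid)
        exo, _, host_aln = preprocess.remove_host_reads(sample.reads, pack.host_genome)
        assignments = profiler.assign_reads(exo, marker_index)
        prok = profiler.prokaryote_profile(
            profiler.estimate_abundance(assignments, marker_index, sid)
        )
        if prok.empty:
            continue
        gf = taxa.group_fractions(prok, taxa.classify_genera(prok, traits))
        results = damage_mod.group_damage(
            exo, pack, habitat, host_aln,
            cycles=cfg.read_length,
            groups=["all", "environmental", "human_related"],
            index_cache=index_cache,
        )
        by = {r.group: r for r in results}
        row = {
            "sample_id": sid,
            "environmental_fraction": 100.0 * gf.environmental,
            "true_environmental_fraction": 100.0 * float(env_f),
        }
        for grp in ("host", "all", "environmental", "human_related"):
            fit = by[grp].fit
            row[f"{grp}_ok"] = fit.ok
            if fit.ok:
                row[f"{grp}_delta_s"] = fit.params.delta_s
                row[f"{grp}_delta_d"] = fit.params.delta_d
                row[f"{grp}_mean_overhang"] = fit.params.mean_overhang
            if by[grp].delta is not None:
                row[f"delta_vs_host_delta_s_{grp}"] = by[grp].delta["delta_s"]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AuthenticationSummary:
    separation: bool  # mean Δδs(environmental) > mean Δδs(human_related)
    mean_delta_ds_environmental: float
    mean_delta_ds_human_related: float
    bin_means_microbial_delta_s: list
    host_slope_pvalue: float


def summarize_authentication(cohort: pd.DataFrame) -> AuthenticationSummary:
    """Separation and binning diagnostics for one or more pooled cohorts."""
    env = cohort["delta_vs_host_delta_s_environmental"].dropna()
    hum = cohort["delta_vs_host_delta_s_human_related"].dropna()
    binned = damage_mod.bin_by_environmental_fraction(
        cohort.rename(columns={"all_delta_s": "microbial_delta_s"})[
            ["environmental_fraction", "microbial_delta_s", "host_delta_s"]
        ].dropna()
    )
    ok = cohort.dropna(subset=["host_delta_s"])
    slope = stats.linregress(ok["environmental_fraction"], ok["host_delta_s"])
    return AuthenticationSummary(
        separation=env.mean() > hum.mean(),
        mean_delta_ds_environmental=float(env.mean()),
        mean_delta_ds_human_related=float(hum.mean()),
        bin_means_microbial_delta_s=binned["microbial_delta_s_mean"].tolist(),
        host_slope_pvalue=float(slope.pvalue),
    )


MIXTURE_PROPORTIONS = (0.30, 0.25, 0.18, 0.12, 0.10, 0.05)


def mixture_pack(seed: int = 0) -> simkit.ReferencePack:
    return simkit.build_reference_pack(
        {"environmental": 2, "oral": 2, "gut_other": 1, "pathogen": 1},
        genome_length=20_000, markers_per_taxon=5, marker_length=400, seed=seed,
    )


def mixture_profiling(
    seed: int, n_reads: int = 100_000,
    proportions=MIXTURE_PROPORTIONS,
) -> pd.DataFrame:
    """Profile a known six-taxon community; returns configured vs estimated
    species proportions (all taxa modern — the check isolates profiling)."""
    pack = mixture_pack(0)
    taxa_ids = sorted(pack.genomes)
    marker_index = profiler.MarkerIndex(
        pack.marker_sequences(),
        {
            row["marker_id"]: {k: row[k] for k in ("kingdom",) + simkit.RANKS}
            for _, row in pack.marker_taxonomy().iterrows()
        },
    )
    cfg = SimConfig(
        community=[(t, p, "modern") for t, p in zip(taxa_ids, proportions)],
        n_reads=n_reads, seed=seed,
    )
    sample = simkit.simulate_sample(pack, cfg, f"mix{seed}")
    profile = profiler.estimate_abundance(
        profiler.assign_reads(sample.reads, marker_index), marker_index
    )
    return pd.DataFrame(
        {
            "species": taxa_ids,
            "configured": list(proportions),
            "estimated": [profile.at("species").get(t, 0.0) for t in taxa_ids],
        }
    ), profile


def shallow_vs_deep(seed: int, n_reads: int = 60_000, fraction: float = 0.1,
                    rank: str = "class") -> float | None:
    """Pearson R between a deep sample's profile and the profile of its
    uniform subsample at ``fraction`` of the reads."""
    pack = standard_pack(0)
    marker_index = profiler.MarkerIndex(
        pack.marker_sequences(),
        {
            row["marker_id"]: {k: row[k] for k in ("kingdom",) + simkit.RANKS}
            for _, row in pack.marker_taxonomy().iterrows()
        },
    )
    taxa_ids = sorted(pack.genomes)
    props = np.linspace(2.0, 0.5, len(taxa_ids))
    props /= props.sum()
    cfg = SimConfig(
        community=[(t, float(p), "modern") for t, p in zip(taxa_ids, props)],
        n_reads=n_reads, seed=seed,
    )
    sample = simkit.simulate_sample(pack, cfg, f"deep{seed}")
    deep = profiler.estimate_abundance(
        profiler.assign_reads(sample.reads, marker_index), marker_index
    )
    shallow_reads = simkit.subsample_reads(sample.reads, fraction, seed=seed)
    shallow = profiler.estimate_abundance(
        profiler.assign_reads(shallow_reads, marker_index), marker_index
    )
    return profiler.compare_profiles(deep, shallow, rank)


def shared_class(pack: simkit.ReferencePack) -> str:
    """A taxonomy class containing both environmental and human-related
    taxa (the durable-class control requires one)."""
    for cls in sorted({lin["class"] for lin in pack.taxonomy.values()}):
        habitats = {
            pack.traits[t].habitat == "environmental"
            for t in pack.taxa_of_class(cls)
            if pack.traits[t].habitat
        }
        if habitats == {True, False}:
            return cls
    raise ValueError("no class spans environmental and human-related taxa")


def single_class_control(
    seed: int, n_reads: int = 5000, params: DamageParams = ANCIENT,
    pack: simkit.ReferencePack | None = None, index_cache: dict | None = None,
) -> dict:
    """Restrict the damage comparison to one taxonomy class.

    Emulates the durable-taxon control: if the environmental-vs-human
    damage difference reflected taxon biology rather than age, restricting
    both groups to a single class would erase it. Returns the fitted
    delta_s per group within the shared class.
    """
    pack = pack or standard_pack(0)
    cls = shared_class(pack)
    subset = set(pack.taxa_of_class(cls))
    habitat = {t: tr.habitat for t, tr in pack.traits.items() if tr.habitat}
    cfg = _cohort_sample_config(pack, 0.5, n_reads, 0.2, seed, params)
    sample = simkit.simulate_sample(pack, cfg, f"cls{seed}")
    exo, _, host_aln = preprocess.remove_host_reads(sample.reads, pack.host_genome)
    results = damage_mod.group_damage(
        exo, pack, habitat, host_aln,
        groups=["environmental", "human_related"],
        taxa_subset=subset, index_cache=index_cache,
    )
    by = {r.group: r for r in results}
    out = {"class": cls}
    for grp in ("environmental", "human_related"):
        fit = by[grp].fit
        out[grp] = fit.params.delta_s if fit.ok else None
    return out
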