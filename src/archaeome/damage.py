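"""Position-specific misincorporation profiles and damage-model estimation.

The authentication logic of the package: tally C→T (from the 5' end) and
G→A (from the 3' end) substitution opportunities per read position, fit the
terminal-deamination model by maximum likelihood, and compare fitted damage
between taxon groups and the endogenous host DNA of the same sample.

Model: the expected C→T frequency at 5' position x (1-based) is

    f(x) = delta_s * (1 - lam)**x + delta_d * (1 - (1 - lam)**x)

with the mirrored form for 3' G→A, plus a sequencing-error floor fixed from
the pooled transversion rate (transversions carry no deamination signal).
The fit maximizes a product of per-position binomial likelihoods
Binom(k | n, f(x)) over both ends: a coarse grid scan followed by bounded
local refinement from the best grid points. Uncertainty comes from a
read-resampling bootstrap (percentile intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from ._rng import substream
from ._seq import C as _C, G as _G, T as _T, A as _A, is_transversion, revcomp
from . import preprocess
from .records import AlignmentRecord
from .simkit import DamageParams, ReferencePack

DAMAGE_GROUPS = ("environmental", "human_related", "oral", "gut", "pathogen")
_HABITAT_TO_GROUP = {"oral": "oral", "gut_other": "gut", "pathogen": "pathogen"}


@dataclass
class MisincorporationProfile:
    """Per-position substitution opportunity/observation counts.

    ``five_prime`` counts reference-C opportunities (``n_C``) and observed
    C→T (``k_CT``) at positions 1..K from the read's 5' end; ``three_prime``
    the mirrored G→A counts measured from the 3' end. ``background`` pools
    transversion counts for the error-floor estimate. Optional per-read
    opportunity matrices support read-level bootstrap resampling.
    """

    K: int
    n_C: np.ndarray
    k_CT: np.ndarray
    n_G: np.ndarray
    k_GA: np.ndarray
    n_background: int = 0
    k_background: int = 0
    per_read: dict | None = None

    def __post_init__(self) -> None:
        if self.K < 5:
            raise ValueError("window K must be >= 5")
        for n, k in ((self.n_C, self.k_CT), (self.n_G, self.k_GA)):
            if np.any(k > n) or np.any(k < 0):
                raise ValueError("invalid counts: need 0 <= k <= n at every position")

    @property
    def epsilon_hat(self) -> float:
        """Error floor from the pooled transversion rate: each specific
        substitution type occurs at epsilon/3 per opportunity."""
        if self.n_background == 0:
            return 0.0
        return 3.0 * self.k_background / self.n_background

    def frequencies(self, end: str = "5p") -> np.ndarray:
        n, k = (self.n_C, self.k_CT) if end == "5p" else (self.n_G, self.k_GA)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, k / np.maximum(n, 1), np.nan)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for x in range(self.K):
            rows.append({"end": "5p", "position": x + 1, "ref_base": "C",
                         "n": int(self.n_C[x]), "k": int(self.k_CT[x])})
        for x in range(self.K):
            rows.append({"end": "3p", "position": x + 1, "ref_base": "G",
                         "n": int(self.n_G[x]), "k": int(self.k_GA[x])})
        return pd.DataFrame(rows, columns=["end", "position", "ref_base", "n", "k"])


def tally_misincorporations(
    alignments: Iterable[AlignmentRecord],
    references: Mapping[str, str],
    K: int = 25,
    cycles: int | None = None,
    collect_per_read: bool = False,
) -> MisincorporationProfile:
    """Tally per-position C→T / G→A opportunities from ungapped alignments.

    Reference segments are re-oriented to read coordinates for minus-strand
    alignments. All non-C→T/G→A transversions are pooled into the
    background used for the error floor. When ``cycles`` is given, reads of
    exactly that length are excluded from the 3'-end tally: such reads hit
    the sequencer's cycle limit, so their 3' terminus need not be a fragment
    end and would dilute the terminal G→A signal.
    """
    n_C = np.zeros(K, dtype=np.int64)
    k_CT = np.zeros(K, dtype=np.int64)
    n_G = np.zeros(K, dtype=np.int64)
    k_GA = np.zeros(K, dtype=np.int64)
    n_bg = 0
    k_bg = 0
    pr_nC, pr_kCT, pr_nG, pr_kGA = [], [], [], []

    for aln in alignments:
        ref = references.get(aln.reference_id)
        if ref is None:
            raise KeyError(f"reference {aln.reference_id!r} not provided")
        L = aln.read_length
        if aln.ref_start + L > len(ref):
            raise ValueError(
                f"alignment of {aln.read_id} overruns reference {aln.reference_id}"
            )
        refseg = ref[aln.ref_start : aln.ref_start + L]
        if aln.strand == "-":
            refseg = revcomp(refseg)
        seg = np.frombuffer(refseg.encode("ascii"), dtype=np.uint8)
        use_3p = cycles is None or L < cycles
        W = min(K, L)
        c5 = (seg[:W] == _C).astype(np.int64)
        n_C[:W] += c5
        g3 = (seg[::-1][:W] == _G).astype(np.int64)
        if use_3p:
            n_G[:W] += g3
        r_kCT = np.zeros(K, dtype=np.int64)
        r_kGA = np.zeros(K, dtype=np.int64)
        for pos, rb, qb in aln.mismatches:
            if rb == "C" and qb == "T" and pos <= K:
                r_kCT[pos - 1] += 1
            y = L - pos + 1
            if rb == "G" and qb == "A" and y <= K and use_3p:
                r_kGA[y - 1] += 1
            if is_transversion(rb, qb):
                k_bg += 1
        n_bg += 2 * L  # two transversion alternatives per aligned base
        k_CT += r_kCT
        k_GA += r_kGA
        if collect_per_read:
            rc5 = np.zeros(K, dtype=np.uint8)
            rc5[:W] = c5
            rg3 = np.zeros(K, dtype=np.uint8)
            if use_3p:
                rg3[:W] = g3
            pr_nC.append(rc5)
            pr_kCT.append(r_kCT.astype(np.uint8))
            pr_nG.append(rg3)
            pr_kGA.append(r_kGA.astype(np.uint8))

    per_read = None
    if collect_per_read and pr_nC:
        per_read = {
            "n_C": np.array(pr_nC, dtype=np.float32),
            "k_CT": np.array(pr_kCT, dtype=np.float32),
            "n_G": np.array(pr_nG, dtype=np.float32),
            "k_GA": np.array(pr_kGA, dtype=np.float32),
        }
    return MisincorporationProfile(K, n_C, k_CT, n_G, k_GA, n_bg, k_bg, per_read)


@dataclass
class FittedDamage:
    """Point estimates plus bootstrap intervals for one damage fit."""

    params: DamageParams | None
    loglik: float = float("nan")
    converged: bool = False
    lambda_identifiable: bool = True
    insufficient: bool = False
    message: str = ""
    n_reads: int = 0
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.converged and not self.insufficient

    def as_dict(self) -> dict:
        d = {
            "delta_s": self.params.delta_s if self.params else float("nan"),
            "delta_d": self.params.delta_d if self.params else float("nan"),
            "lam": self.params.lam if self.params else float("nan"),
            "mean_overhang": self.params.mean_overhang if self.params else float("nan"),
            "epsilon": self.params.epsilon if self.params else float("nan"),
            "loglik": self.loglik,
            "converged": self.converged,
            "insufficient": self.insufficient,
            "n_reads": self.n_reads,
        }
        for p, (lo, hi) in self.ci.items():
            d[f"{p}_ci_low"], d[f"{p}_ci_high"] = lo, hi
        return d


def model_frequency(x: np.ndarray, delta_s: float, delta_d: float, lam: float,
                    eps_type: float = 0.0) -> np.ndarray:
    """f(x) with the per-type error floor folded in."""
    decay = (1.0 - lam) ** np.asarray(x, dtype=float)
    d = delta_s * decay + delta_d * (1.0 - decay)
    return d + (1.0 - d) * eps_type


def _negloglik(theta, x, n5, k5, n3, k3, eps_type):
    ds, dd, lam = theta
    f = np.clip(model_frequency(x, ds, dd, lam, eps_type), 1e-12, 1 - 1e-12)
    ll = np.sum(k5 * np.log(f) + (n5 - k5) * np.log1p(-f))
    ll += np.sum(k3 * np.log(f) + (n3 - k3) * np.log1p(-f))
    return -ll


_GRID_DS = np.arange(0.0, 0.5001, 0.05)
_GRID_DD = np.arange(0.0, 0.5001, 0.05)
_GRID_LAM = np.arange(0.05, 0.9501, 0.05)


def _grid_scan(x, n5, k5, n3, k3, eps_type):
    ds, dd, lam = np.meshgrid(_GRID_DS, _GRID_DD, _GRID_LAM, indexing="ij")
    theta = np.stack([ds.ravel(), dd.ravel(), lam.ravel()], axis=1)
    decay = (1.0 - theta[:, 2:3]) ** x[None, :]
    d = theta[:, 0:1] * decay + theta[:, 1:2] * (1.0 - decay)
    f = np.clip(d + (1.0 - d) * eps_type, 1e-12, 1 - 1e-12)
    ll = (k5[None, :] * np.log(f) + (n5 - k5)[None, :] * np.log1p(-f)).sum(axis=1)
    ll += (k3[None, :] * np.log(f) + (n3 - k3)[None, :] * np.log1p(-f)).sum(axis=1)
    return theta, ll


def _fit_counts(x, n5, k5, n3, k3, eps_type, bounds):
    theta, ll = _grid_scan(x, n5, k5, n3, k3, eps_type)
    order = np.argsort(ll)[::-1]
    best_grid_ll = float(ll[order[0]])
    best = (theta[order[0]], best_grid_ll)
    for i in order[:3]:
        res = optimize.minimize(
            _negloglik,
            theta[i],
            args=(x, n5, k5, n3, k3, eps_type),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if -res.fun > best[1]:
            best = (res.x, -res.fun)
    return np.asarray(best[0], dtype=float), float(best[1]), best_grid_ll


def fit_damage_model(
    profile: MisincorporationProfile,
    bounds: Sequence[tuple[float, float]] = ((0.0, 1.0), (0.0, 1.0), (1e-3, 0.95)),
    n_bootstrap: int = 200,
    seed: int = 0,
    min_opportunities: int = 500,
) -> FittedDamage:
    """Maximum-likelihood fit of (delta_s, delta_d, lam) to a profile.

    The error floor epsilon is fixed from the profile's pooled transversion
    rate, not co-estimated. Coarse grid scan (delta in 0..0.5 step 0.05,
    lam in 0.05..0.95 step 0.05) seeds L-BFGS-B refinement from the best 3
    grid points; the refined likelihood never falls below the best grid
    likelihood. The upper bound on lam stays below 1: as lam -> 1 the
    overhang term (1 - lam)**x vanishes and delta_s drifts along an
    unidentifiable ridge, so undamaged data would report arbitrary delta_s;
    capping lam pins delta_s to the observed terminal excess instead.
    Bootstrap intervals resample reads when per-read counts are
    available, else fall back to a position-wise binomial resample.
    Profiles with fewer than ``min_opportunities`` C or G opportunities
    return an "insufficient data" result instead of an estimate.
    """
    n5, k5 = profile.n_C.astype(float), profile.k_CT.astype(float)
    n3, k3 = profile.n_G.astype(float), profile.k_GA.astype(float)
    n_reads = len(profile.per_read["n_C"]) if profile.per_read else 0
    if n5.sum() < min_opportunities or n3.sum() < min_opportunities:
        return FittedDamage(
            None, insufficient=True, n_reads=n_reads,
            message=f"fewer than {min_opportunities} C or G opportunities",
        )
    eps = profile.epsilon_hat
    eps_type = eps / 3.0
    x = np.arange(1, profile.K + 1, dtype=float)

    if k5.sum() + k3.sum() == 0 and eps == 0.0:
        # degenerate likelihood: no substitutions at all
        return FittedDamage(
            DamageParams(0.0, 0.0, 1.0, 0.0), loglik=0.0, converged=True,
            lambda_identifiable=False, n_reads=n_reads,
            message="no substitutions observed; lambda unidentifiable",
        )

    theta_hat, ll, grid_ll = _fit_counts(x, n5, k5, n3, k3, eps_type, bounds)
    params = DamageParams(
        float(np.clip(theta_hat[0], 0, 1)),
        float(np.clip(theta_hat[1], 0, 1)),
        float(np.clip(theta_hat[2], 1e-3, 1.0)),
        eps,
    )
    result = FittedDamage(
        params, loglik=ll, converged=ll >= grid_ll - 1e-9, n_reads=n_reads
    )
    if not result.converged:
        result.message = "refinement fell below grid optimum"

    if n_bootstrap > 0:
        rng = substream(seed, "damage-bootstrap")
        draws = {"delta_s": [], "delta_d": [], "mean_overhang": [], "lam": []}
        for _ in range(n_bootstrap):
            if profile.per_read:
                R = n_reads
                w = rng.multinomial(R, np.full(R, 1.0 / R)).astype(np.float32)
                b_n5 = w @ profile.per_read["n_C"]
                b_k5 = w @ profile.per_read["k_CT"]
                b_n3 = w @ profile.per_read["n_G"]
                b_k3 = w @ profile.per_read["k_GA"]
            else:
                # parametric fallback: position-wise binomial resample
                p5 = np.where(n5 > 0, k5 / np.maximum(n5, 1), 0.0)
                p3 = np.where(n3 > 0, k3 / np.maximum(n3, 1), 0.0)
                b_n5, b_n3 = n5, n3
                b_k5 = rng.binomial(n5.astype(int), p5).astype(float)
                b_k3 = rng.binomial(n3.astype(int), p3).astype(float)
            th, _, _ = _fit_counts(
                x, b_n5.astype(float), b_k5.astype(float),
                b_n3.astype(float), b_k3.astype(float), eps_type, bounds,
            )
            draws["delta_s"].append(th[0])
            draws["delta_d"].append(th[1])
            draws["lam"].append(th[2])
            draws["mean_overhang"].append(1.0 / max(th[2], 1e-3) - 1.0)
        for p, vals in draws.items():
            lo, hi = np.percentile(vals, [2.5, 97.5])
            point = getattr(params, p) if p != "mean_overhang" else params.mean_overhang
            result.ci[p] = (float(min(lo, point)), float(max(hi, point)))
    return result


def metropolis_sample(
    profile: MisincorporationProfile,
    n_iter: int = 5000,
    burn_in: int = 1000,
    step: float = 0.02,
    seed: int = 0,
) -> dict[str, float]:
    """Random-walk Metropolis over the same binomial likelihood; returns
    posterior means (flat priors on the bounded cube). Provided as an
    alternative summary to the MLE; the pipeline consumes the MLE."""
    rng = substream(seed, "metropolis")
    x = np.arange(1, profile.K + 1, dtype=float)
    n5, k5 = profile.n_C.astype(float), profile.k_CT.astype(float)
    n3, k3 = profile.n_G.astype(float), profile.k_GA.astype(float)
    eps_type = profile.epsilon_hat / 3.0
    lo = np.array([0.0, 0.0, 1e-3])
    hi = np.array([1.0, 1.0, 1.0])
    theta = np.array([0.1, 0.01, 0.3])
    cur = -_negloglik(theta, x, n5, k5, n3, k3, eps_type)
    kept = []
    for it in range(n_iter):
        prop = theta + rng.normal(0, step, 3)
        if np.any(prop < lo) or np.any(prop > hi):
            pass
        else:
            new = -_negloglik(prop, x, n5, k5, n3, k3, eps_type)
            if np.log(rng.random()) < new - cur:
                theta, cur = prop, new
        if it >= burn_in:
            kept.append(theta.copy())
    kept = np.array(kept)
    return {
        "delta_s": float(kept[:, 0].mean()),
        "delta_d": float(kept[:, 1].mean()),
        "lam": float(kept[:, 2].mean()),
        "mean_overhang": float((1.0 / kept[:, 2] - 1.0).mean()),
    }


def select_representative_species(
    profiles: Sequence, threshold: float = 0.10
) -> list[str]:
    """Species reaching at least ``threshold`` relative abundance in at
    least one sample (the representative-genome selection rule)."""
    selected: set[str] = set()
    for p in profiles:
        for sp, ab in p.at("species").items():
            if ab >= threshold:
                selected.add(sp)
    return sorted(selected)


@dataclass
class GroupDamageResult:
    """Fitted damage for one taxon group, with Δ statistics vs the host.

    Δ is host − group for each of delta_s, delta_d and 1/lam − 1, so
    undamaged (modern) groups yield positive Δdelta_s.
    """

    group: str
    fit: FittedDamage
    delta: dict[str, float] | None = None


def group_subsets(
    classifications: Mapping[str, str], taxa_subset: set[str] | None = None
) -> dict[str, list[str]]:
    """Taxon-id subsets per damage group from habitat labels
    (taxon -> habitat in {environmental, oral, gut_other, pathogen})."""
    subsets: dict[str, list[str]] = {g: [] for g in DAMAGE_GROUPS}
    for tid, habitat in classifications.items():
        if taxa_subset is not None and tid not in taxa_subset:
            continue
        if habitat == "environmental":
            subsets["environmental"].append(tid)
        elif habitat in _HABITAT_TO_GROUP:
            subsets[_HABITAT_TO_GROUP[habitat]].append(tid)
            subsets["human_related"].append(tid)
    return {g: sorted(t) for g, t in subsets.items()}


def group_damage(
    reads: Sequence,
    pack: ReferencePack,
    classifications: Mapping[str, str],
    host_alignments: Sequence[AlignmentRecord],
    K: int = 25,
    cycles: int | None = 75,
    max_mismatches: int = 5,
    n_bootstrap: int = 0,
    seed: int = 0,
    min_opportunities: int = 500,
    groups: Sequence[str] | None = None,
    taxa_subset: set[str] | None = None,
    index_cache: dict | None = None,
) -> list[GroupDamageResult]:
    """Fit damage per taxon group and difference it against the host.

    Reads are mapped independently against each group's genome subset (a
    read may contribute to several groups), tallied and fitted; the host
    fit uses the supplied host alignments. Groups whose genome subset is
    empty or whose mapped data falls below the opportunity floor are
    flagged, leaving other groups unaffected.
    """
    requested = list(groups) if groups is not None else ["all"] + list(DAMAGE_GROUPS)
    subsets = group_subsets(classifications, taxa_subset)
    all_taxa = sorted(
        t for t in classifications
        if (taxa_subset is None or t in taxa_subset) and t in pack.genomes
    )
    subsets["all"] = all_taxa

    host_refs = {"host": pack.host_genome}
    host_profile = tally_misincorporations(host_alignments, host_refs, K, cycles)
    host_fit = fit_damage_model(
        host_profile, n_bootstrap=n_bootstrap, seed=seed,
        min_opportunities=min_opportunities,
    )
    results = [GroupDamageResult("host", host_fit, None)]

    for grp in requested:
        taxa = subsets.get(grp, [])
        refs = {t: pack.genomes[t] for t in taxa if t in pack.genomes}
        if not refs:
            results.append(
                GroupDamageResult(
                    grp,
                    FittedDamage(None, insufficient=True, message="empty genome subset"),
                )
            )
            continue
        cache_key = (grp, frozenset(refs))
        if index_cache is not None and cache_key in index_cache:
            index = index_cache[cache_key]
        else:
            index = preprocess.ReferenceIndex(refs)
            if index_cache is not None:
                index_cache[cache_key] = index
        alignments = preprocess.map_reads(reads, index, max_mismatches=max_mismatches)
        prof = tally_misincorporations(alignments, refs, K, cycles)
        fit = fit_damage_model(
            prof, n_bootstrap=n_bootstrap, seed=seed,
            min_opportunities=min_opportunities,
        )
        delta = None
        if fit.ok and host_fit.ok:
            delta = {
                "delta_s": host_fit.params.delta_s - fit.params.delta_s,
                "delta_d": host_fit.params.delta_d - fit.params.delta_d,
                "mean_overhang": host_fit.params.mean_overhang - fit.params.mean_overhang,
            }
        results.append(GroupDamageResult(grp, fit, delta))
    return results


_BIN_LABELS = ("0-25", "25-50", "50-75", "75-100")


def assign_bin(environmental_percent: float) -> str:
    """Bin an environmental fraction (percent): left-closed right-open
    except the last bin, which includes 100."""
    if not 0.0 <= environmental_percent <= 100.0:
        raise ValueError("environmental fraction must be within [0, 100] percent")
    return _BIN_LABELS[min(int(environmental_percent // 25), 3)]


def bin_by_environmental_fraction(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-bin mean and standard deviation of damage parameters.

    ``samples`` must contain ``environmental_fraction`` (percent, 0-100);
    every other numeric column (e.g. microbial_delta_s, host_delta_s) is
    summarized per bin. Empty bins appear with NaN summaries.
    """
    df = samples.copy()
    df["bin"] = df["environmental_fraction"].map(assign_bin)
    value_cols = [
        c for c in df.columns
        if c not in ("bin", "environmental_fraction", "sample_id")
        and pd.api.types.is_numeric_dtype(df[c])
    ]
    grouped = df.groupby("bin")
    rows = []
    for label in _BIN_LABELS:
        row: dict = {"bin": label, "n_samples": 0}
        if label in grouped.groups:
            sub = grouped.get_group(label)
            row["n_samples"] = len(sub)
            for c in value_cols:
                row[f"{c}_mean"] = float(sub[c].mean())
                row[f"{c}_sd"] = float(sub[c].std(ddof=1)) if len(sub) > 1 else float("nan")
        else:
            for c in value_cols:
                row[f"{c}_mean"] = float("nan")
                row[f"{c}_sd"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def write_fits(results: Sequence[GroupDamageResult], path) -> None:
    rows = [{"group": r.group, **r.fit.as_dict(),
             **({f"delta_{k}": v for k, v in r.delta.items()} if r.delta else {})}
            for r in results]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
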