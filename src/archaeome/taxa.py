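"""Habitat classification of genera and trait summaries.

Genera are divided into environmental vs human-related groups, the latter
split into oral, potential-pathogen and other (gut etc.) subgroups. The
classification rule is conservative: a genus counts as human-related only
if *every* species of that genus observed in the dataset is human-related —
a single observed environmental species makes the whole genus
environmental. Classification therefore depends on the species observed,
not on the full known membership of the genus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .profiler import AbundanceProfile
from .simkit import TaxonTraits

HUMAN_SUBGROUPS = ("oral", "gut_other", "pathogen")
GROUPS = ("environmental", "oral", "pathogen", "other")


def load_trait_table(path_or_df) -> dict[str, TaxonTraits]:
    """species -> traits from a TSV (species, genus, habitat, gram,
    respiration) or an equivalent DataFrame."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(
        path_or_df, sep="\t", dtype=str
    )
    out: dict[str, TaxonTraits] = {}
    for _, row in df.iterrows():
        out[row["species"]] = TaxonTraits(
            habitat=row.get("habitat") or None,
            gram=(row.get("gram") if row.get("gram") not in (None, "NA", "") else None),
            respiration=(
                row.get("respiration")
                if row.get("respiration") not in (None, "NA", "")
                else None
            ),
        )
    return out


def classify_genus(genus: str, species_habitats: Mapping[str, str]) -> str:
    """Classify one genus from the habitats of its *observed* species.

    Any observed environmental species makes the genus environmental.
    Otherwise the genus is human-related, with the subgroup taken by
    unanimity, else by majority of observed species, remaining ties
    resolving to ``gut_other``.
    """
    if not species_habitats:
        raise ValueError(f"genus {genus!r}: no observed species")
    for sp, hab in species_habitats.items():
        if hab is None or hab == "" or pd.isna(hab):
            raise ValueError(f"species {sp!r} in genus {genus!r} lacks a habitat annotation")
        if hab not in ("environmental",) + HUMAN_SUBGROUPS:
            raise ValueError(f"species {sp!r}: unknown habitat {hab!r}")
    habitats = list(species_habitats.values())
    if "environmental" in habitats:
        return "environmental"
    counts = Counter(habitats)
    if len(counts) == 1:
        return habitats[0]
    top = counts.most_common()
    if top[0][1] > top[1][1]:
        return top[0][0]
    return "gut_other"


def classify_genera(
    profile: AbundanceProfile, traits: Mapping[str, TaxonTraits]
) -> dict[str, str]:
    """Classify every genus present in a (prokaryote-renormalized)
    profile, using only the species observed in it."""
    by_genus: dict[str, dict[str, str]] = {}
    for sp in profile.at("species"):
        if sp not in traits:
            raise KeyError(f"species {sp!r} missing from the trait table")
        genus = profile.lineages[sp]["genus"]
        by_genus.setdefault(genus, {})[sp] = traits[sp].habitat
    return {g: classify_genus(g, obs) for g, obs in by_genus.items()}


@dataclass
class GroupFractions:
    """Per-sample abundance fractions over the four habitat groups."""

    sample_id: str
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"group fractions sum to {total}, not 1")

    @property
    def environmental(self) -> float:
        return self.fractions.get("environmental", 0.0)

    @property
    def human_related(self) -> float:
        return 1.0 - self.environmental


def group_fractions(
    profile: AbundanceProfile, classifications: Mapping[str, str]
) -> GroupFractions:
    """Sum genus abundances into {environmental, oral, pathogen, other}.

    The profile is expected at genus rank over prokaryotes (renormalized);
    every genus must be classified.
    """
    fractions = {g: 0.0 for g in GROUPS}
    for genus, ab in profile.at("genus").items():
        if genus not in classifications:
            raise KeyError(f"genus {genus!r} is unclassified")
        label = classifications[genus]
        fractions["other" if label == "gut_other" else label] += ab
    return GroupFractions(profile.sample_id, fractions)


def trait_summary(
    classifications: Mapping[str, str],
    traits: Mapping[str, TaxonTraits],
    profiles: Sequence[AbundanceProfile],
    weighted: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Per-group percentages of gram stain and respiratory type.

    By default percentages are abundance-weighted population shares, with
    species abundance pooled across the supplied profiles; ``weighted=False``
    counts each species once. Within each dichotomy (gram; respiration) the
    percentages sum to 100 per group. Species with missing trait values are
    excluded from the corresponding dichotomy and reported.
    """
    weights: dict[str, float] = {}
    for p in profiles:
        for sp, ab in p.at("species").items():
            weights[sp] = weights.get(sp, 0.0) + (ab if weighted else 0.0)
    if not weighted:
        weights = {sp: 1.0 for sp in weights}

    gram_levels = ("positive", "negative")
    resp_levels = ("aerobic", "facultative_aerobic", "anaerobic", "facultative_anaerobic")
    acc: dict[str, dict[str, float]] = {}
    excluded = {"gram": [], "respiration": []}
    genus_of: dict[str, str] = {}
    for p in profiles:
        for sp in p.at("species"):
            genus_of[sp] = p.lineages[sp]["genus"]
    for sp, w in weights.items():
        genus = genus_of[sp]
        label = classifications.get(genus)
        if label is None:
            raise KeyError(f"genus {genus!r} is unclassified")
        group = "other" if label == "gut_other" else label
        tr = traits.get(sp)
        if tr is None:
            raise KeyError(f"species {sp!r} missing from the trait table")
        row = acc.setdefault(group, {})
        if tr.gram in gram_levels:
            row[f"gram_{tr.gram}"] = row.get(f"gram_{tr.gram}", 0.0) + w
        else:
            excluded["gram"].append(sp)
        if tr.respiration in resp_levels:
            row[tr.respiration] = row.get(tr.respiration, 0.0) + w
        else:
            excluded["respiration"].append(sp)

    rows = []
    for group in sorted(acc):
        row = {"group": group}
        gtot = sum(acc[group].get(f"gram_{g}", 0.0) for g in gram_levels)
        for g in gram_levels:
            row[f"gram_{g}"] = 100.0 * acc[group].get(f"gram_{g}", 0.0) / gtot if gtot else float("nan")
        rtot = sum(acc[group].get(r, 0.0) for r in resp_levels)
        for r in resp_levels:
            row[r] = 100.0 * acc[group].get(r, 0.0) / rtot if rtot else float("nan")
        rows.append(row)
    cols = ["group", "gram_positive", "gram_negative", *resp_levels]
    return pd.DataFrame(rows, columns=cols), excluded


def group_fraction_table(fracs: Sequence[GroupFractions]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": f.sample_id,
                **{g: f.fractions.get(g, 0.0) for g in GROUPS},
                "human_related": f.human_related,
            }
            for f in fracs
        ]
    )
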