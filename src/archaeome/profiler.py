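"""Clade-specific-marker taxonomic profiling.

A simplified marker-gene profiler in the spirit of clade-specific-marker
tools: exogenous reads are assigned to marker sequences (unique-best
mapping, species-level ties discarded, coordinate duplicates removed), and
species abundance is estimated from length-normalized marker coverage with
decile trimming, then aggregated up the taxonomy to class/family/genus
ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from . import preprocess
from .records import AlignmentRecord, ReadRecord
from .simkit import RANKS, PROKARYOTE_KINGDOMS

KINGDOM_GROUPS = {
    "bacteria": "bacteria_archaea",
    "archaea": "bacteria_archaea",
    "viruses": "viruses",
    "viroids": "viruses",
    "eukaryotes": "eukaryotes",
}


@dataclass
class MarkerIndex:
    """Marker sequences plus the clade registry they resolve to."""

    sequences: dict[str, str]
    lineages: dict[str, dict[str, str]]  # marker_id -> {kingdom, class, ..., species}
    _ref_index: object = None

    def __post_init__(self) -> None:
        for mid, seq in self.sequences.items():
            if len(seq) == 0:
                raise ValueError(f"marker {mid} has zero length")
            if mid not in self.lineages:
                raise KeyError(f"marker {mid!r} has no taxonomy entry")
            if not self.lineages[mid].get("species"):
                raise ValueError(f"marker {mid} does not resolve to a species-level clade")

    @property
    def marker_lengths(self) -> dict[str, int]:
        return {mid: len(s) for mid, s in self.sequences.items()}

    def clades(self, rank: str) -> list[str]:
        return sorted({lin[rank] for lin in self.lineages.values()})

    def species_lineage(self) -> dict[str, dict[str, str]]:
        """species -> lineage (one entry per species)."""
        out: dict[str, dict[str, str]] = {}
        for lin in self.lineages.values():
            out[lin["species"]] = lin
        return out

    def reference_index(self, seed_length: int = 16) -> preprocess.ReferenceIndex:
        if self._ref_index is None:
            self._ref_index = preprocess.ReferenceIndex(self.sequences, seed_length)
        return self._ref_index


def build_marker_index(markers, taxonomy) -> MarkerIndex:
    """Build a :class:`MarkerIndex` from a FASTA (path or mapping
    marker_id -> sequence) and a taxonomy table (path to TSV or DataFrame
    with columns marker_id, kingdom, class, family, genus, species)."""
    if isinstance(markers, (str, bytes)) or hasattr(markers, "__fspath__"):
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(markers), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate marker id {rec.id!r} in FASTA")
            seqs[rec.id] = str(rec.seq).upper()
    else:
        seqs = dict(markers)
    if isinstance(taxonomy, pd.DataFrame):
        tax = taxonomy
    else:
        tax = pd.read_csv(taxonomy, sep="\t", dtype=str)
    if "marker_id" not in tax.columns:
        if len(tax) == 0 and not seqs:
            return MarkerIndex({}, {})
        raise ValueError("taxonomy table must have a marker_id column")
    if tax["marker_id"].duplicated().any():
        dup = tax.loc[tax["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValueError(f"duplicate marker id {dup!r} in taxonomy table")
    lineages = {
        row["marker_id"]: {k: row[k] for k in ("kingdom",) + RANKS}
        for _, row in tax.iterrows()
    }
    missing = set(seqs) - set(lineages)
    if missing:
        raise KeyError(f"markers without taxonomy entries: {sorted(missing)[:5]}")
    lineages = {mid: lin for mid, lin in lineages.items() if mid in seqs}
    return MarkerIndex(seqs, lineages)


def assign_reads(
    reads: Iterable[ReadRecord],
    index: MarkerIndex,
    seed_length: int = 16,
    max_mismatches: int = 5,
) -> pd.DataFrame:
    """Assign reads to markers; returns a table after duplicate removal.

    Reads whose best placements span markers of more than one species are
    discarded (the unique-marker philosophy); ties within a species resolve
    to the lexicographically smallest (marker, start, strand). Coordinate
    duplicates are then collapsed before counting.
    """
    ref_index = index.reference_index(seed_length)
    hits = preprocess.map_reads_all_best(reads, ref_index, seed_length, max_mismatches)
    alignments: list[AlignmentRecord] = []
    for read, placements in hits:
        species = {index.lineages[rid]["species"] for rid, _, _ in placements}
        if len(species) != 1:
            continue
        rid, start, strand = min(placements)
        alignments.append(
            preprocess._make_alignment(read, ref_index, rid, start, strand)
        )
    alignments = preprocess.deduplicate(alignments)
    rows = [
        {
            "read_id": a.read_id,
            "marker_id": a.reference_id,
            "species": index.lineages[a.reference_id]["species"],
            "kingdom": index.lineages[a.reference_id]["kingdom"],
            "ref_start": a.ref_start,
            "strand": a.strand,
            "read_length": a.read_length,
            "n_mismatches": a.n_mismatches,
        }
        for a in alignments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "marker_id",
            "species",
            "kingdom",
            "ref_start",
            "strand",
            "read_length",
            "n_mismatches",
        ],
    )


@dataclass
class AbundanceProfile:
    """Per-sample relative abundances at class/family/genus/species ranks.

    Abundances at each rank sum to 1 (or the profile is empty), and each
    rank's abundances are exact sums of its children's.
    """

    sample_id: str
    abundances: dict[str, dict[str, float]]
    n_assigned_reads: int = 0
    lineages: dict[str, dict[str, str]] = field(default_factory=dict)
    empty: bool = False
    warning: str = ""

    def at(self, rank: str) -> dict[str, float]:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        return self.abundances.get(rank, {})

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"sample": self.sample_id, "rank": rank, "clade": clade, "abundance": ab}
            for rank in RANKS
            for clade, ab in sorted(self.at(rank).items())
        ]
        return pd.DataFrame(rows, columns=["sample", "rank", "clade", "abundance"])


def _aggregate_ranks(
    species_ab: Mapping[str, float], lineages: Mapping[str, Mapping[str, str]]
) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {r: {} for r in RANKS}
    out["species"] = dict(species_ab)
    for rank in ("genus", "family", "class"):
        agg: dict[str, float] = {}
        for sp, ab in species_ab.items():
            clade = lineages[sp][rank]
            agg[clade] = agg.get(clade, 0.0) + ab
        out[rank] = agg
    return out


def estimate_abundance(
    assignments: pd.DataFrame, index: MarkerIndex, sample_id: str = "sample"
) -> AbundanceProfile:
    """Coverage-based relative abundance from marker assignments.

    Per-marker coverage = assigned bases / marker length. Per species the
    coverage is a robust mean over its markers: when a species has >= 10
    markers, markers in the top and bottom decile of coverage are excluded
    (zero-coverage markers included beforehand); otherwise a plain mean.
    Relative abundance is coverage normalized across species; higher ranks
    aggregate by summation.
    """
    lengths = index.marker_lengths
    species_lineage = index.species_lineage()
    marker_bases = (
        assignments.groupby("marker_id")["read_length"].sum().to_dict()
        if len(assignments)
        else {}
    )
    by_species: dict[str, list[float]] = {}
    for mid, lin in index.lineages.items():
        cov = marker_bases.get(mid, 0) / lengths[mid]
        by_species.setdefault(lin["species"], []).append(cov)
    coverage: dict[str, float] = {}
    for sp, covs in by_species.items():
        covs = sorted(covs)
        if len(covs) >= 10:
            t = len(covs) // 10
            covs = covs[t : len(covs) - t]
        coverage[sp] = float(np.mean(covs))
    total = sum(coverage.values())
    if total <= 0:
        return AbundanceProfile(
            sample_id, {r: {} for r in RANKS}, 0, {}, empty=True,
            warning="zero total marker coverage",
        )
    species_ab = {sp: c / total for sp, c in coverage.items() if c > 0}
    return AbundanceProfile(
        sample_id,
        _aggregate_ranks(species_ab, species_lineage),
        int(len(assignments)),
        {sp: dict(species_lineage[sp]) for sp in species_ab},
    )


def kingdom_breakdown(assignments: pd.DataFrame, index: MarkerIndex) -> dict[str, float]:
    """Fractions of assigned reads per kingdom group
    {bacteria_archaea, viruses, eukaryotes}; empty input gives an empty
    mapping (with a warning)."""
    if len(assignments) == 0:
        warnings.warn("no assigned reads; kingdom breakdown undefined")
        return {}
    groups = assignments["kingdom"].map(KINGDOM_GROUPS)
    counts = groups.value_counts()
    total = counts.sum()
    return {g: float(c) / total for g, c in counts.items()}


def prokaryote_profile(profile: AbundanceProfile) -> AbundanceProfile:
    """Renormalize a profile over bacterial/archaeal species only (the
    prokaryote-only view consumed by habitat classification and damage
    grouping)."""
    keep = {
        sp: ab
        for sp, ab in profile.at("species").items()
        if profile.lineages[sp]["kingdom"] in PROKARYOTE_KINGDOMS
    }
    total = sum(keep.values())
    if total <= 0:
        return AbundanceProfile(
            profile.sample_id, {r: {} for r in RANKS}, 0, {}, empty=True,
            warning="no prokaryote abundance",
        )
    species_ab = {sp: ab / total for sp, ab in keep.items()}
    lineages = {sp: profile.lineages[sp] for sp in species_ab}
    return AbundanceProfile(
        profile.sample_id,
        _aggregate_ranks(species_ab, lineages),
        profile.n_assigned_reads,
        lineages,
    )


def compare_profiles(
    p1: AbundanceProfile, p2: AbundanceProfile, rank: str = "species"
) -> float | None:
    """Pearson R between two profiles over the union of clades at ``rank``
    (absent clade = 0). Returns None when either zero-padded vector is
    constant, where the correlation is undefined."""
    a1, a2 = p1.at(rank), p2.at(rank)
    if not a1 or not a2:
        raise ValueError(f"both profiles must be non-empty at rank {rank!r}")
    clades = sorted(set(a1) | set(a2))
    v1 = np.array([a1.get(c, 0.0) for c in clades])
    v2 = np.array([a2.get(c, 0.0) for c in clades])
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        return None
    return float(stats.pearsonr(v1, v2).statistic)


def write_profiles(profiles: Sequence[AbundanceProfile], path) -> None:
    pd.concat([p.to_long() for p in profiles], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
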