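"""Synthetic references, communities and damaged single-end reads.

This module emulates shotgun sequencing of a mixed community recovered from
buried human remains: a host ("endogenous") genome plus environmental, oral,
gut and pathogen taxa. Sources flagged as ancient carry cytosine-deamination
damage concentrated at fragment termini (elevated C→T at 5' ends and,
after blunt-end repair, G→A at 3' ends, both decaying geometrically with
distance from the end); modern sources carry only baseline sequencing error.
Every emitted read is recorded in a ground-truth table so downstream stages
can be tested without any real data.

Damage model
------------
A fragment receives independent 5' and 3' single-stranded overhangs whose
lengths follow a geometric law, P(L >= x) = (1 - lam)**x, so the mean
overhang length is 1/lam - 1.  Cytosines inside an overhang deaminate with
probability ``delta_s`` (single-stranded), cytosines in the double-stranded
interior with probability ``delta_d``.  Blunt-end repair removes 3'
overhangs and fills in 5' overhangs of the complementary strand, so on the
sequenced strand the 3' terminus shows the mirrored G→A signal.  The
expected C→T frequency at 5' position x (1-based) is therefore

    f(x) = delta_s * (1 - lam)**x + delta_d * (1 - (1 - lam)**x)

plus a small sequencing-error floor.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from ._seq import C, G, T, A, random_sequence, revcomp, seq_to_u8, u8_to_seq

RANKS = ("class", "family", "genus", "species")
PROKARYOTE_KINGDOMS = frozenset({"bacteria", "archaea"})
HABITATS = ("environmental", "oral", "gut_other", "pathogen")
GRAM = ("positive", "negative")
RESPIRATION = ("aerobic", "facultative_aerobic", "anaerobic", "facultative_anaerobic")


@dataclass(frozen=True)
class DamageParams:
    """Parameters of the terminal-deamination damage model.

    delta_s, delta_d : deamination probability per cytosine in
        single-stranded overhangs / the double-stranded interior.
    lam : per-base termination probability of the geometric overhang-length
        distribution; ``mean_overhang`` = 1/lam - 1.
    epsilon : baseline per-base substitution (sequencing error) probability.
    """

    delta_s: float
    delta_d: float
    lam: float
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        for name in ("delta_s", "delta_d", "lam", "epsilon"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.lam <= 0:
            raise ValueError("lam must be > 0 (lam=1 means no overhangs)")

    @property
    def mean_overhang(self) -> float:
        return 1.0 / self.lam - 1.0

    @classmethod
    def modern(cls, epsilon: float = 0.001) -> "DamageParams":
        """Undamaged (contemporary) source: sequencing error only."""
        return cls(0.0, 0.0, 1.0, epsilon)


@dataclass(frozen=True)
class TaxonTraits:
    habitat: str | None
    gram: str | None
    respiration: str | None


@dataclass(frozen=True)
class Marker:
    marker_id: str
    taxon_id: str
    start: int
    end: int  # half-open


@dataclass
class ReferencePack:
    """Synthetic stand-in for a set of representative prokaryote genomes plus
    a clade-specific marker database and a habitat/trait table."""

    genomes: dict[str, str]
    host_genome: str
    markers: list[Marker]
    taxonomy: dict[str, dict[str, str]]  # taxon -> {kingdom, class, family, genus, species}
    traits: dict[str, TaxonTraits]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.markers:
            if m.marker_id in seen:
                raise ValueError(f"duplicate marker id {m.marker_id}")
            seen.add(m.marker_id)
            genome = self.genomes.get(m.taxon_id)
            if genome is None:
                raise ValueError(f"marker {m.marker_id} references unknown taxon {m.taxon_id}")
            if not (0 <= m.start < m.end <= len(genome)):
                raise ValueError(f"marker {m.marker_id} coordinates outside its genome")
        for tid in self.genomes:
            lin = self.taxonomy.get(tid)
            if lin is None or any(r not in lin for r in ("kingdom",) + RANKS):
                raise ValueError(f"taxon {tid} lacks a complete lineage")

    def marker_sequences(self) -> dict[str, str]:
        return {
            m.marker_id: self.genomes[m.taxon_id][m.start : m.end] for m in self.markers
        }

    def marker_taxonomy(self) -> pd.DataFrame:
        rows = []
        for m in self.markers:
            lin = self.taxonomy[m.taxon_id]
            rows.append({"marker_id": m.marker_id, **{k: lin[k] for k in ("kingdom",) + RANKS}})
        return pd.DataFrame(rows, columns=["marker_id", "kingdom", *RANKS])

    def trait_table(self) -> pd.DataFrame:
        rows = []
        for tid, tr in self.traits.items():
            lin = self.taxonomy[tid]
            rows.append(
                {
                    "species": lin["species"],
                    "genus": lin["genus"],
                    "habitat": tr.habitat,
                    "gram": tr.gram,
                    "respiration": tr.respiration,
                }
            )
        return pd.DataFrame(rows, columns=["species", "genus", "habitat", "gram", "respiration"])

    def taxa_of_habitat(self, habitat: str) -> list[str]:
        return sorted(t for t, tr in self.traits.items() if tr.habitat == habitat)

    def taxa_of_class(self, class_name: str) -> list[str]:
        return sorted(t for t, lin in self.taxonomy.items() if lin["class"] == class_name)


def build_reference_pack(
    n_taxa_per_group: Mapping[str, int],
    genome_length: int = 20_000,
    markers_per_taxon: int = 5,
    marker_length: int = 400,
    host_genome_length: int = 40_000,
    species_per_genus: int = 1,
    n_classes: int = 4,
    seed: int = 0,
) -> ReferencePack:
    """Generate a deterministic synthetic reference pack.

    ``n_taxa_per_group`` maps a group name — one of the prokaryote habitats
    (environmental, oral, gut_other, pathogen) or ``virus``/``eukaryote`` —
    to the number of taxa to generate. Genomes are i.i.d. uniform
    nucleotides; each genome carries ``markers_per_taxon`` non-overlapping
    marker subsequences tagged with the owning clade at every rank. Classes
    are drawn from a shared pool cycling across groups, so (as for real
    bacterial classes such as Actinobacteria) one class can contain both
    environmental and human-related taxa.
    """
    if genome_length < 750:
        raise ValueError("genome_length must be at least 10x a typical 75 bp read")
    if markers_per_taxon > 0 and markers_per_taxon * marker_length > genome_length:
        raise ValueError(
            f"markers_per_taxon ({markers_per_taxon}) x marker_length ({marker_length}) "
            f"= {markers_per_taxon * marker_length} exceeds genome_length ({genome_length})"
        )
    for g, n in n_taxa_per_group.items():
        if g not in HABITATS + ("virus", "eukaryote"):
            raise ValueError(f"unknown group {g!r}")
        if n < 0:
            raise ValueError("taxon counts must be >= 0")

    genomes: dict[str, str] = {}
    markers: list[Marker] = []
    taxonomy: dict[str, dict[str, str]] = {}
    traits: dict[str, TaxonTraits] = {}
    family_counter = 0
    taxon_counter = 0

    for group in sorted(n_taxa_per_group):
        n_taxa = n_taxa_per_group[group]
        for i in range(n_taxa):
            tid = f"{group}_{i:03d}"
            rng = substream(seed, "genome", tid)
            genomes[tid] = random_sequence(genome_length, rng)
            genus_idx = i // species_per_genus
            family_idx = i // max(1, 2 * species_per_genus)
            if group == "virus":
                kingdom, habitat = "viruses", None
            elif group == "eukaryote":
                kingdom, habitat = "eukaryotes", None
            elif group == "gut_other" and i % 2 == 1:
                kingdom, habitat = "archaea", group
            else:
                kingdom, habitat = "bacteria", group
            class_name = f"class_{(family_counter + family_idx) % max(1, n_classes):02d}"
            taxonomy[tid] = {
                "kingdom": kingdom,
                "class": class_name,
                "family": f"{group}_f{family_idx:02d}",
                "genus": f"{group}_g{genus_idx:02d}",
                "species": tid,
            }
            traits[tid] = TaxonTraits(
                habitat=habitat,
                gram=GRAM[taxon_counter % 2] if habitat else None,
                respiration=RESPIRATION[taxon_counter % 4] if habitat else None,
            )
            spacing = genome_length // markers_per_taxon if markers_per_taxon else 0
            for m in range(markers_per_taxon):
                start = m * spacing
                markers.append(Marker(f"{tid}_m{m}", tid, start, start + marker_length))
            taxon_counter += 1
        family_counter += (n_taxa + max(1, 2 * species_per_genus) - 1) // max(
            1, 2 * species_per_genus
        )

    host = random_sequence(host_genome_length, substream(seed, "host_genome"))
    return ReferencePack(genomes, host, markers, taxonomy, traits)


@dataclass
class SimConfig:
    """Study design of one synthetic sample.

    ``community`` lists (taxon_id, proportion, damage) triples; ``damage``
    may be a :class:`DamageParams`, the string ``"modern"`` or ``None``
    (both meaning sequencing error only, at ``modern_epsilon``).
    Proportions plus ``host_fraction`` must sum to 1.
    """

    community: list[tuple]
    n_reads: int
    host_fraction: float = 0.0
    host_damage: object = "modern"
    read_length: int = 75
    fragment_mean: float = 60.0
    fragment_sd: float = 15.0
    fragment_min: int = 25
    quality: int = 37
    modern_epsilon: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.host_fraction + sum(p for _, p, *_ in self.community)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"community proportions + host_fraction sum to {total}, not 1")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_length < 25:
            raise ValueError("read_length must be >= 25")

    def resolve_damage(self, spec) -> DamageParams:
        if spec is None or spec == "modern":
            return DamageParams.modern(self.modern_epsilon)
        if isinstance(spec, DamageParams):
            return spec
        raise TypeError(f"cannot interpret damage spec {spec!r}")


def simulate_fragments(
    genome: str,
    n: int,
    fragment_length: tuple[float, float, int] = (60.0, 15.0, 25),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int, str]]:
    """Draw ``n`` fragment placements ``(start, length, strand)``.

    Lengths are normal(mean, sd) rounded and truncated to
    [min, genome length]; starts are uniform over valid positions; strands
    uniform. A zero sd gives fixed-length fragments.
    """
    if len(genome) == 0:
        raise ValueError("cannot simulate fragments from an empty genome")
    if n < 0:
        raise ValueError("n must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    mean, sd, fmin = fragment_length
    fmin = min(int(fmin), len(genome))
    if sd > 0:
        lengths = np.rint(rng.normal(mean, sd, n)).astype(int)
    else:
        lengths = np.full(n, int(round(mean)))
    lengths = np.clip(lengths, fmin, len(genome))
    starts = (rng.random(n) * (len(genome) - lengths + 1)).astype(int)
    strands = rng.integers(0, 2, n)
    return [
        (int(s), int(l), "+-"[int(st)]) for s, l, st in zip(starts, lengths, strands)
    ]


def apply_damage(
    fragment: str,
    params: DamageParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    return_positions: bool = False,
):
    """Damage one fragment (given 5'→3' on its sequenced strand).

    Draws independent geometric 5' and 3' overhang lengths, deaminates
    overhang cytosines at ``delta_s`` and interior cytosines at ``delta_d``
    (C→T); the 3' terminus shows the mirrored G→A signal fixed in by
    blunt-end repair. Finally every base is substituted uniformly to one of
    the other three bases with probability ``epsilon``. Read length is never
    changed. With ``return_positions`` also returns the 1-based positions of
    deamination events (sequencing errors excluded).
    """
    if len(fragment) == 0:
        raise ValueError("fragment must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = seq_to_u8(fragment).copy()
    L = len(arr)
    l5 = int(rng.geometric(params.lam)) - 1 if params.lam < 1.0 else 0
    l3 = int(rng.geometric(params.lam)) - 1 if params.lam < 1.0 else 0
    idx = np.arange(L)
    ss5 = idx < l5
    ss3 = idx >= L - l3
    interior = ~ss5 & ~ss3
    u = rng.random(L)
    is_c = arr == C
    is_g = arr == G
    # 5' overhang: ss C->T only; 3' terminus (filled in from the complementary
    # strand's overhang): ss G->A only; ds interior: both at delta_d.
    ct = is_c & ((ss5 & (u < params.delta_s)) | (interior & (u < params.delta_d)))
    ga = is_g & ((ss3 & (u < params.delta_s)) | (interior & (u < params.delta_d)))
    arr[ct] = T
    arr[ga] = A
    damaged = np.flatnonzero(ct | ga)
    if params.epsilon > 0:
        err = rng.random(L) < params.epsilon
        if err.any():
            # substitute to a uniformly chosen different base
            base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
            cur = np.searchsorted(base_codes, arr[err])
            shift = rng.integers(1, 4, int(err.sum()))
            arr[err] = base_codes[(cur + shift) % 4]
    out = u8_to_seq(arr)
    if return_positions:
        return out, [int(p) + 1 for p in damaged]
    return out


@dataclass
class SimulatedSample:
    """Reads plus their ground truth for one synthetic sample."""

    sample_id: str
    reads: list
    truth: pd.DataFrame

    def reads_by_source(self, taxon_id: str) -> list:
        ids = set(self.truth.loc[self.truth.taxon_id == taxon_id, "read_id"])
        return [r for r in self.reads if r.read_id in ids]


def simulate_sample(
    pack: ReferencePack, config: SimConfig, sample_id: str = "sample"
) -> SimulatedSample:
    """Simulate one sample's worth of single-end reads with ground truth.

    Read counts per source are multinomial with the configured proportions;
    each read is the first ``read_length`` bases of a damaged fragment.
    The truth table records, per read: source taxon ("host" for the host
    genome), fragment coordinates, strand, and deaminated read positions.
    """
    from .records import ReadRecord

    sources: list[tuple[str, float, DamageParams]] = []
    for entry in config.community:
        tid, prop, dmg = entry[0], entry[1], (entry[2] if len(entry) > 2 else "modern")
        if tid not in pack.genomes:
            raise KeyError(f"community taxon {tid!r} not present in reference pack")
        sources.append((tid, prop, config.resolve_damage(dmg)))
    if config.host_fraction > 0:
        sources.append(("host", config.host_fraction, config.resolve_damage(config.host_damage)))

    rng = substream(config.seed, "sample", sample_id)
    props = np.array([p for _, p, _ in sources], dtype=float)
    counts = rng.multinomial(config.n_reads, props / props.sum()) if sources else []

    qual_char = chr(33 + config.quality)
    reads: list[ReadRecord] = []
    rows: list[dict] = []
    read_no = 0
    for (tid, _, dmg), count in zip(sources, counts):
        genome = pack.host_genome if tid == "host" else pack.genomes[tid]
        frag_rng = substream(config.seed, "fragments", sample_id, tid)
        dmg_rng = substream(config.seed, "damage", sample_id, tid)
        frags = simulate_fragments(
            genome,
            int(count),
            (config.fragment_mean, config.fragment_sd, config.fragment_min),
            rng=frag_rng,
        )
        for start, length, strand in frags:
            frag = genome[start : start + length]
            if strand == "-":
                frag = revcomp(frag)
            damaged_seq, positions = apply_damage(
                frag, dmg, rng=dmg_rng, return_positions=True
            )
            seq = damaged_seq[: config.read_length]
            positions = [p for p in positions if p <= len(seq)]
            rid = f"{sample_id}_r{read_no:07d}"
            reads.append(ReadRecord(rid, seq, qual_char * len(seq)))
            rows.append(
                {
                    "read_id": rid,
                    "taxon_id": tid,
                    "start": start,
                    "end": start + length,
                    "strand": strand,
                    "damaged_positions": ",".join(map(str, positions)),
                }
            )
            read_no += 1
    truth = pd.DataFrame(
        rows, columns=["read_id", "taxon_id", "start", "end", "strand", "damaged_positions"]
    )
    return SimulatedSample(sample_id, reads, truth)


def truth_alignments(sample: SimulatedSample, pack: ReferencePack) -> list:
    """Ground-truth alignment records for every read of a simulated sample.

    Uses the truth table's coordinates instead of a mapper, recovering
    mismatches by direct comparison to the source genome; useful for
    testing downstream stages independently of read mapping. Reads
    truncated at the sequencer cycle limit align to the 5' portion of
    their fragment.
    """
    from .records import AlignmentRecord

    out = []
    truth = sample.truth.set_index("read_id")
    for read in sample.reads:
        row = truth.loc[read.read_id]
        tid = row["taxon_id"]
        genome = pack.host_genome if tid == "host" else pack.genomes[tid]
        L = len(read.sequence)
        start, end, strand = int(row["start"]), int(row["end"]), row["strand"]
        if strand == "+":
            ref_start = start
            refseg = genome[ref_start : ref_start + L]
        else:
            # read is the revcomp of the fragment's 3' ... but sequencing
            # starts from the fragment's 5' end on the sequenced strand,
            # which is the reference interval's end for a minus read
            ref_start = end - L
            refseg = revcomp(genome[ref_start:end])
        mismatches = tuple(
            (i + 1, rb, qb)
            for i, (rb, qb) in enumerate(zip(refseg, read.sequence))
            if rb != qb
        )
        out.append(AlignmentRecord(read.read_id, tid, ref_start, strand, L, mismatches))
    return out


def subsample_reads(reads: Sequence, fraction: float, seed: int = 0) -> list:
    """Uniform without-replacement subsample of a read list (shallow-vs-deep
    sequencing emulation)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = substream(seed, "subsample")
    n = int(round(fraction * len(reads)))
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in sorted(idx)]


def write_fastq(reads: Iterable, path) -> None:
    """Write reads as Sanger FASTQ; a ``.gz`` suffix selects gzip output."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qualities}\n")


def fastq_bytes(reads: Iterable) -> bytes:
    buf = io.StringIO()
    for r in reads:
        buf.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qualities}\n")
    return buf.getvalue().encode("ascii")


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def expected_ct_frequency(x, params: DamageParams) -> np.ndarray:
    """Closed-form expected C→T frequency at 5' position ``x`` (1-based),
    including the sequencing-error floor (a C is mis-read as T with
    probability epsilon/3)."""
    x = np.asarray(x, dtype=float)
    decay = (1.0 - params.lam) ** x
    d = params.delta_s * decay + params.delta_d * (1.0 - decay)
    e = params.epsilon / 3.0
    return d * (1.0 - params.epsilon) + (1.0 - d) * e
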