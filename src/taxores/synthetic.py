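"""Hierarchical sequence simulator with rank-dependent divergence.

Generates taxonomy-annotated marker sequences whose pairwise similarities
carry the structure the threshold analysis assumes: a balanced four-rank
taxonomy (order/family/genus/species) evolved from one root sequence, with
substitutions accrued along each rank edge so that similarity strictly
decreases from intra-species pairs through genus, family and order to
inter-order pairs.  A region layout modulates the per-site substitution
rate (conserved cores vs variable regions), and an optional indel-prone
region mimics the length-hypervariable segment seen in some genera
(deletions only, so the true alignment keeps a fixed column set).

Under the substitution scheme (each edge replaces a site with probability
p by a uniformly chosen different base) the expected per-site identity
between two sequences joined by edges with substitution probabilities
p_1..p_k is  1/4 + 3/4 * prod(1 - 4 p_i / 3),  which the tests use as a
closed-form oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .regions import Alignment, Region, RegionMap, load_alignment
from .taxonomy import (
    UNCERTAIN,
    AnnotatedSequence,
    Lineage,
    load_taxonomy,
    write_taxonomy,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class RegionTemplate:
    """One stretch of the simulated molecule: name, length fraction, rate."""

    name: str
    fraction: float
    rate_multiplier: float


def default_region_layout() -> list[RegionTemplate]:
    """An 18S-like mosaic: nine variable regions in conserved linkers.

    Fractions sum to 1 and are scaled to the requested root length at
    simulation time; variable regions cover roughly half the molecule.
    Multipliers are relative substitution rates, later normalised so the
    length-weighted mean is 1 (rank divergences then read as genome-wide
    expected per-site substitution probabilities).
    """
    return [
        RegionTemplate("L0", 0.02, 0.3),
        RegionTemplate("V1", 0.015, 2.6),
        RegionTemplate("L1", 0.05, 0.3),
        RegionTemplate("V2", 0.12, 2.2),
        RegionTemplate("L2", 0.05, 0.3),
        RegionTemplate("V3", 0.05, 1.8),
        RegionTemplate("L3", 0.06, 0.3),
        RegionTemplate("V4", 0.135, 2.1),
        RegionTemplate("L4", 0.05, 0.3),
        RegionTemplate("V5", 0.04, 2.4),
        RegionTemplate("L5", 0.09, 0.3),
        RegionTemplate("V7", 0.05, 2.3),
        RegionTemplate("L7", 0.08, 0.3),
        RegionTemplate("V8", 0.04, 2.0),
        RegionTemplate("L8", 0.08, 0.3),
        RegionTemplate("V9", 0.055, 2.8),
        RegionTemplate("L9", 0.045, 0.3),
    ]


@dataclass
class SimulationConfig:
    """Study-condition knobs for the hierarchical simulator.

    ``rank_divergence`` maps each rank edge to the expected per-site
    substitution probability accrued along it; it must decrease strictly
    from order to intra-species for the S>G>F>O>I similarity structure to
    emerge.  Defaults give about 190 sequences with hundreds of pairs in
    every category.
    """

    n_orders: int = 4
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 3
    sequences_per_species: int = 4
    root_length: int = 1800
    region_layout: list[RegionTemplate] = field(default_factory=default_region_layout)
    rank_divergence: dict[str, float] = field(
        default_factory=lambda: {
            "order": 0.12,
            "family": 0.06,
            "genus": 0.03,
            "species": 0.01,
            "intra": 0.001,
        }
    )
    indel_region: str | None = None
    indel_rate: float = 0.3       # per-edge probability of one deletion event
    max_indel_length: int = 30
    uncertain_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        d = self.rank_divergence
        chain = [d["order"], d["family"], d["genus"], d["species"], d["intra"]]
        if any(v < 0 for v in chain):
            raise ValueError("divergences must be >= 0")
        # the S>G>F>O>I similarity structure requires a strictly decreasing
        # chain; equal values (e.g. all zero) are allowed but degenerate
        if any(b > a for a, b in zip(chain, chain[1:])):
            raise ValueError("rank_divergence must not increase order->intra")
        for n in (
            self.n_orders, self.families_per_order, self.genera_per_family,
            self.species_per_genus, self.sequences_per_species,
        ):
            if n < 1:
                raise ValueError("counts must be >= 1")

    @property
    def n_sequences(self) -> int:
        return (
            self.n_orders * self.families_per_order * self.genera_per_family
            * self.species_per_genus * self.sequences_per_species
        )


@dataclass
class SyntheticDataset:
    """Simulated records plus the true alignment and taxonomy."""

    records: list[AnnotatedSequence]          # ungapped
    alignment: Alignment                      # true alignment (gapped rows)
    taxonomy: dict[str, tuple[str, Lineage]]  # record_id -> (accession, lineage)
    config: SimulationConfig
    region_map: RegionMap

    @property
    def lineages(self) -> dict[str, Lineage]:
        return {rid: lin for rid, (_, lin) in self.taxonomy.items()}


def _instantiate_layout(
    layout: list[RegionTemplate], root_length: int
) -> tuple[RegionMap, np.ndarray]:
    """Turn fractional templates into integer intervals + per-site rates."""
    bounds = np.round(
        np.cumsum([0.0] + [t.fraction for t in layout])
        / sum(t.fraction for t in layout) * root_length
    ).astype(int)
    regions = []
    rates = np.empty(root_length)
    for t, s, e in zip(layout, bounds[:-1], bounds[1:]):
        if e <= s:
            raise ValueError(f"region template {t.name} collapses at this length")
        regions.append(Region(t.name, int(s), int(e)))
        rates[s:e] = t.rate_multiplier
    rates /= rates.mean()  # genome-wide mean multiplier = 1
    return RegionMap(regions), rates


def _mutate(
    seq: np.ndarray, p_site: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Substitute each site with its probability; new base uniform over others."""
    out = seq.copy()
    hit = np.nonzero((rng.random(seq.size) < p_site) & (out != b"-"))[0]
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        codes = np.searchsorted(_BASES, out[hit])
        out[hit] = _BASES[(codes + shift) % 4]
    return out


def _maybe_delete(
    seq: np.ndarray,
    region: Region | None,
    rate: float,
    max_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if region is None or rng.random() >= rate:
        return seq
    length = int(rng.integers(1, max_len + 1))
    live = np.nonzero(seq[region.start : region.end] != b"-")[0]
    if live.size <= length:
        return seq
    start = int(rng.integers(0, live.size - length))
    out = seq.copy()
    out[region.start + live[start : start + length]] = b"-"
    return out


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Run the hierarchical simulation; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    region_map, multipliers = _instantiate_layout(
        config.region_layout, config.root_length
    )
    mean_sim = expected_pair_identity(config, "I")
    if mean_sim < 0.5:
        import warnings

        warnings.warn(
            "expected inter-order identity below 50%; local-alignment "
            "similarities become unreliable",
            stacklevel=2,
        )
    indel_region = region_map[config.indel_region] if config.indel_region else None
    d = config.rank_divergence
    root = _BASES[rng.integers(0, 4, size=config.root_length)]

    rows: list[AnnotatedSequence] = []
    taxonomy: dict[str, tuple[str, Lineage]] = {}
    counter = 0
    for o in range(config.n_orders):
        o_anc = _mutate(root, d["order"] * multipliers, rng)
        o_anc = _maybe_delete(
            o_anc, indel_region, config.indel_rate, config.max_indel_length, rng
        )
        for f in range(config.families_per_order):
            f_anc = _mutate(o_anc, d["family"] * multipliers, rng)
            f_anc = _maybe_delete(
                f_anc, indel_region, config.indel_rate, config.max_indel_length, rng
            )
            for g in range(config.genera_per_family):
                g_anc = _mutate(f_anc, d["genus"] * multipliers, rng)
                g_anc = _maybe_delete(
                    g_anc, indel_region, config.indel_rate,
                    config.max_indel_length, rng,
                )
                for s in range(config.species_per_genus):
                    s_anc = _mutate(g_anc, d["species"] * multipliers, rng)
                    for k in range(config.sequences_per_species):
                        seq = _mutate(s_anc, d["intra"] * multipliers, rng)
                        counter += 1
                        rid = f"seq{counter:04d}"
                        lin = Lineage(
                            order=f"Ord{o + 1}",
                            family=f"Ord{o + 1}_Fam{f + 1}",
                            genus=f"Ord{o + 1}_Fam{f + 1}_Gen{g + 1}",
                            species=(
                                f"Ord{o + 1}_Fam{f + 1}_Gen{g + 1}_Sp{s + 1}"
                            ),
                        )
                        rows.append(
                            AnnotatedSequence(
                                rid, f"SYN{counter:06d}", lin,
                                seq.tobytes().decode(),
                            )
                        )

    if config.uncertain_fraction > 0:
        n_unc = int(round(config.uncertain_fraction * len(rows)))
        picks = rng.choice(len(rows), size=n_unc, replace=False)
        for idx in picks:
            rec = rows[idx]
            lin = rec.lineage
            rows[idx] = AnnotatedSequence(
                rec.record_id, rec.accession,
                Lineage(lin.order, lin.family, lin.genus, UNCERTAIN),
                rec.residues,
            )
    for rec in rows:
        taxonomy[rec.record_id] = (rec.accession, rec.lineage)

    alignment = Alignment(rows)
    records = [
        AnnotatedSequence(r.record_id, r.accession, r.lineage, r.ungapped)
        for r in rows
    ]
    return SyntheticDataset(records, alignment, taxonomy, config, region_map)


def expected_pair_identity(
    config: SimulationConfig, category: str
) -> float:
    """Closed-form expected whole-sequence identity for a pair category.

    Averages the per-site match probability 1/4 + 3/4*prod(1 - 4 p_e/3)
    over the region layout, where the edge set is the path joining two
    sequences whose most recent shared rank matches ``category`` (S =
    same species, ... I = different orders).
    """
    d = config.rank_divergence
    path = {
        "S": ["intra"],
        "G": ["intra", "species"],
        "F": ["intra", "species", "genus"],
        "O": ["intra", "species", "genus", "family"],
        "I": ["intra", "species", "genus", "family", "order"],
    }[category]
    _, multipliers = _instantiate_layout(config.region_layout, config.root_length)
    # both lineages traverse each edge class once (f enters squared)
    prod = np.ones_like(multipliers)
    for edge in path:
        f = 1.0 - 4.0 * np.clip(d[edge] * multipliers, 0.0, 0.75) / 3.0
        prod *= f * f
    return float(np.mean(0.25 + 0.75 * prod))


def emit(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write the dataset in the formats the pipeline consumes.

    Produces ``sequences.fasta`` (ungapped), ``alignment.fasta`` (true
    alignment), ``taxonomy.tsv``, ``regions.yaml`` (the realised region
    map) and ``config.yaml`` (an echo of the generating parameters).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequences": out / "sequences.fasta",
        "alignment": out / "alignment.fasta",
        "taxonomy": out / "taxonomy.tsv",
        "regions": out / "regions.yaml",
        "config": out / "config.yaml",
    }
    with open(paths["sequences"], "w") as fh:
        for rec in dataset.records:
            fh.write(f">{rec.record_id}\n{rec.residues}\n")
    with open(paths["alignment"], "w") as fh:
        for rec in dataset.alignment.rows:
            fh.write(f">{rec.record_id}\n{rec.residues}\n")
    write_taxonomy(dataset.taxonomy, paths["taxonomy"])
    with open(paths["regions"], "w") as fh:
        yaml.safe_dump(
            {
                "regions": [
                    {"name": r.name, "start": r.start + 1, "end": r.end}
                    for r in dataset.region_map.regions
                ]
            },
            fh,
        )
    cfg = asdict(dataset.config)
    cfg["region_layout"] = [asdict(t) for t in dataset.config.region_layout]
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh)
    return paths


def load(out_dir) -> SyntheticDataset:
    """Round-trip loader for :func:`emit` output."""
    out = Path(out_dir)
    with open(out / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    raw["region_layout"] = [RegionTemplate(**t) for t in raw["region_layout"]]
    config = SimulationConfig(**raw)
    alignment = load_alignment(out / "alignment.fasta", out / "taxonomy.tsv")
    taxonomy = load_taxonomy(out / "taxonomy.tsv")
    records = [
        AnnotatedSequence(r.record_id, r.accession, r.lineage, r.ungapped)
        for r in alignment.rows
    ]
    region_map, _ = _instantiate_layout(config.region_layout, config.root_length)
    return SyntheticDataset(records, alignment, taxonomy, config, region_map)
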