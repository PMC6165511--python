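"""Synthetic datasets with the statistical structure the analysis expects.

Emulates the study design end to end: 8 cannulated animals sampled in two
seasons on two diets (a 2x2 crossover), two in-situ substrates incubated at
{24, 36, 48, 72, 96, 120} h, and a bacterial community of ~80 genera nested
in ~10 phyla where two designated phyla dominate (~90% of expected mass).
A small set of "planted" genera carries true effects on the fractional
digestion rate (and optionally the slowly digestible pool), and a few rare
taxa present in only one or two samples provide extreme influence points for
the Cook's-distance filter.

Everything is driven by a single integer seed: identical configurations give
bit-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .community import TaxonTable
from .kinetics import FRACTIONS, DigestionTimeCourse, UnitKey

logger = logging.getLogger(__name__)

CLADE_NAMES = ("phylum", "class", "order", "family", "genus")

# mild, fixed per-fraction modulation of the base kinetic parameters so the
# three fiber fractions give distinct but correlated response columns
_FRACTION_MODS = {
    "NDF": (1.0, 1.0, 1.0),
    "cellulose": (0.9, 1.05, 1.08),
    "hemicellulose": (1.1, 0.95, 0.92),
}


class SimError(ValueError):
    """Raised on invalid simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Design and distributional parameters of one synthetic dataset."""

    n_animals: int = 8
    seasons: tuple[str, ...] = ("spring", "fall")
    diets: tuple[str, ...] = ("hay", "straw")
    substrates: tuple[str, ...] = ("hay", "straw")
    times_h: tuple[float, ...] = (24.0, 36.0, 48.0, 72.0, 96.0, 120.0)
    n_phyla: int = 10
    n_classes: int = 14
    n_orders: int = 20
    n_families: int = 40
    n_genera: int = 80
    n_planted: int = 3
    effect_sizes: tuple[float, ...] = (0.004, 0.003, -0.004)
    extent_effect_sizes: tuple[float, ...] = ()
    base_params: dict = field(
        default_factory=lambda: {
            "hay": (5.0, 60.0, 0.022),
            "straw": (5.0, 70.0, 0.017),
        }
    )
    obs_noise: float = 1.0
    abundance_concentration: float = 8.0
    dominant_share: float = 0.92
    n_rare_taxa: int = 2
    rare_prevalence: int = 1
    rare_intensity: float = 0.25
    min_rate: float = 1e-4
    drop_one_animal_in_fall: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_animals", "n_phyla", "n_classes", "n_orders",
                     "n_families", "n_genera"):
            if getattr(self, name) < 1:
                raise SimError(f"{name} must be >= 1")
        if self.n_planted < 0 or self.n_planted > self.n_genera:
            raise SimError("n_planted must be in [0, n_genera]")
        if len(self.effect_sizes) < self.n_planted:
            raise SimError("need one effect size per planted genus")
        t = np.asarray(self.times_h, float)
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise SimError("times must be positive and strictly increasing")
        if self.obs_noise < 0:
            raise SimError("obs_noise must be >= 0")
        if self.abundance_concentration <= 0:
            raise SimError("abundance_concentration must be > 0")
        if not set(self.substrates) <= set(self.base_params):
            raise SimError("base_params must cover every substrate")
        if self.n_rare_taxa >= self.n_genera:
            raise SimError("rare taxa must leave at least one common genus")

    @property
    def n_samples(self) -> int:
        n = self.n_animals * len(self.seasons) * len(self.diets)
        if self.drop_one_animal_in_fall and "fall" in self.seasons:
            n -= len(self.diets)
        return n


@dataclass
class GroundTruth:
    """Planted effects and per-unit true kinetic parameters."""

    planted_genus_ids: list[str]
    gamma: dict[str, float]            # rate effect per standardized unit
    gamma_extent: dict[str, float]     # optional effect on the b pool
    unit_params: pd.DataFrame          # unit x fraction -> true a, b, c

    def __post_init__(self) -> None:
        for gid in self.planted_genus_ids:
            if gid not in self.gamma:
                raise SimError(f"planted genus {gid} lacks an effect size")


def make_taxonomy(config: SimConfig) -> dict[str, tuple[str, ...]]:
    """Build a proper 5-level lineage tree with exactly n_genera leaves.

    Each genus gets a lineage phylum;class;order;family;genus.  Intermediate
    clades are assigned round-robin to their parents so the nesting is a
    tree (every clade has exactly one parent).
    """
    rng = np.random.default_rng(config.seed)

    def _names(prefix: str, n: int) -> list[str]:
        return [f"{prefix}{i + 1:02d}" for i in range(n)]

    counts = (config.n_phyla, config.n_classes, config.n_orders,
              config.n_families, config.n_genera)
    # children counts may not exceed parents is not required, but a child
    # level needs at least as many labels as parents to cover each parent
    names = [_names(level[0].upper() + level[1:3], c)
             for level, c in zip(CLADE_NAMES, counts)]
    parent_of: list[np.ndarray] = []
    for lvl in range(1, len(counts)):
        n_child, n_parent = counts[lvl], counts[lvl - 1]
        # round-robin guarantees every parent has a child when possible
        assignment = np.arange(n_child) % n_parent
        rng.shuffle(assignment)
        parent_of.append(assignment)

    lineages: dict[str, tuple[str, ...]] = {}
    for g in range(config.n_genera):
        idx = g
        chain = [names[-1][g]]
        for lvl in range(len(counts) - 1, 0, -1):
            idx = int(parent_of[lvl - 1][idx])
            chain.append(names[lvl - 1][idx])
        lineages[names[-1][g]] = tuple(reversed(chain))
    return lineages


def _sample_index(config: SimConfig) -> pd.Index:
    animals = [f"ox{i + 1}" for i in range(config.n_animals)]
    rows = []
    for season in config.seasons:
        present = animals
        if config.drop_one_animal_in_fall and season == "fall":
            present = animals[:-1]
        for diet in config.diets:
            for animal in present:
                rows.append((animal, season, diet))
    return pd.MultiIndex.from_tuples(rows, names=["animal", "season", "diet"])


def simulate_community(config: SimConfig) -> tuple[TaxonTable, GroundTruth]:
    """Draw the samples x genera proportion table and the ground truth.

    Genus intensities are log-normal around phylum-level expected weights
    (two dominant phyla hold ``dominant_share`` of expected mass) and closed
    to proportions per sample; heavy tails are intentional so the influence
    filter has something to do.  The last ``n_rare_taxa`` genera are zeroed
    everywhere except ``rare_prevalence`` randomly chosen samples, where they
    spike.
    """
    index = _sample_index(config)
    n_samples = len(index)
    if config.n_rare_taxa and config.rare_prevalence > n_samples:
        raise SimError(
            f"rare_prevalence={config.rare_prevalence} exceeds {n_samples} samples"
        )
    rng = np.random.default_rng(config.seed + 1)
    lineages = make_taxonomy(config)
    genera = list(lineages)

    phylum_of = np.array(
        [list(lineages[g])[0] for g in genera]
    )
    phyla = sorted(set(phylum_of))
    # expected phylum weights: two dominants split the configured share,
    # the rest share the remainder geometrically
    weights = {}
    dom = phyla[:2]
    if len(phyla) >= 2:
        weights[dom[0]] = 0.6 * config.dominant_share
        weights[dom[1]] = 0.4 * config.dominant_share
        rest = phyla[2:]
        if rest:
            tail = np.array([0.6**k for k in range(len(rest))])
            tail = tail / tail.sum() * (1.0 - config.dominant_share)
            for ph, w in zip(rest, tail):
                weights[ph] = w
    else:
        weights[phyla[0]] = 1.0

    base = np.empty(len(genera))
    for ph in phyla:
        members = np.flatnonzero(phylum_of == ph)
        # uneven split within a phylum: geometric ranks, shuffled
        ranks = 0.7 ** np.arange(len(members))
        rng.shuffle(ranks)
        base[members] = weights[ph] * ranks / ranks.sum()

    sigma = 1.0 / np.sqrt(config.abundance_concentration)
    noise = rng.normal(0.0, sigma, size=(n_samples, len(genera)))
    intensity = base[None, :] * np.exp(noise - sigma**2 / 2.0)

    rare_ids = genera[len(genera) - config.n_rare_taxa:] if config.n_rare_taxa else []
    for j, gid in enumerate(rare_ids):
        col = genera.index(gid)
        intensity[:, col] = 0.0
        hit = rng.choice(n_samples, size=config.rare_prevalence, replace=False)
        intensity[hit, col] = config.rare_intensity

    props = intensity / intensity.sum(axis=1, keepdims=True)
    data = pd.DataFrame(props, index=index, columns=genera)

    # planted genera: common taxa only, spread across the table
    eligible = [g for g in genera if g not in rare_ids]
    planted = [eligible[i * max(1, len(eligible) // max(config.n_planted, 1))]
               for i in range(config.n_planted)]
    gamma = {g: 0.0 for g in genera}
    gamma_ext = {g: 0.0 for g in genera}
    for gid, eff in zip(planted, config.effect_sizes):
        gamma[gid] = float(eff)
    for gid, eff in zip(planted, config.extent_effect_sizes):
        gamma_ext[gid] = float(eff)

    flat = data.copy()
    flat.index = ["|".join(map(str, t)) for t in index]
    table = TaxonTable(data=flat, lineages=lineages, mode="proportions")
    truth = GroundTruth(
        planted_genus_ids=planted,
        gamma=gamma,
        gamma_extent=gamma_ext,
        unit_params=pd.DataFrame(),
    )
    return table, truth


def sample_key(animal: str, season: str, diet: str) -> str:
    return f"{animal}|{season}|{diet}"


def simulate_kinetics(
    config: SimConfig, community: TaxonTable, truth: GroundTruth
) -> list[DigestionTimeCourse]:
    """Generate digestion time courses whose rates depend on the community.

    For each unit the true rate is ``c = c0 * fraction_mod + sum_j gamma_j *
    z_ij`` where ``z_ij`` is the standardised proportion of planted genus j
    in the unit's sample; observations add Gaussian noise of sd ``obs_noise``
    and are clipped into [0, 100].  Rates that would go non-positive are
    floored at ``min_rate`` and logged.  True parameters are recorded in
    ``truth.unit_params``.
    """
    rng = np.random.default_rng(config.seed + 2)
    data = community.data
    z = pd.DataFrame(index=data.index)
    for gid in truth.planted_genus_ids:
        col = data[gid]
        sd = col.std(ddof=1)
        z[gid] = (col - col.mean()) / sd if sd > 0 else 0.0

    t = np.asarray(config.times_h, float)
    courses: list[DigestionTimeCourse] = []
    records = []
    floored = 0
    for (animal, season, diet) in _sample_index(config):
        skey = sample_key(animal, season, diet)
        if skey not in data.index:
            raise SimError(f"community table lacks sample {skey}")
        rate_shift = sum(
            truth.gamma[g] * z.at[skey, g] for g in truth.planted_genus_ids
        )
        ext_shift = sum(
            truth.gamma_extent[g] * z.at[skey, g] for g in truth.planted_genus_ids
        )
        for substrate in config.substrates:
            a0, b0, c0 = config.base_params[substrate]
            for fraction in FRACTIONS:
                fa, fb, fc = _FRACTION_MODS[fraction]
                a = a0 * fa
                b = max(b0 * fb + ext_shift, 0.0)
                c = c0 * fc + rate_shift
                if c < config.min_rate:
                    floored += 1
                    c = config.min_rate
                mean = a + b * (1.0 - np.exp(-c * t))
                obs = mean + rng.normal(0.0, config.obs_noise, size=t.size)
                obs = np.clip(obs, 0.0, 100.0)
                key = UnitKey(animal, season, diet, substrate, fraction)
                courses.append(DigestionTimeCourse(key, t.copy(), obs))
                records.append(
                    {
                        "animal": animal,
                        "season": season,
                        "diet": diet,
                        "substrate": substrate,
                        "fraction": fraction,
                        "a": a,
                        "b": b,
                        "c": c,
                    }
                )
    if floored:
        logger.warning("floored %d non-positive rates at %g", floored,
                       config.min_rate)
    truth.unit_params = pd.DataFrame.from_records(records)
    return courses


@dataclass
class SyntheticDataset:
    """A full generated dataset plus its ground truth."""

    config: SimConfig
    community: TaxonTable
    truth: GroundTruth
    timecourses: list[DigestionTimeCourse]
    metadata: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Run the whole generator: taxonomy, community, kinetics, metadata."""
    community, truth = simulate_community(config)
    courses = simulate_kinetics(config, community, truth)
    meta = pd.DataFrame(
        [
            {"sample": sample_key(a, s, d), "animal": a, "season": s, "diet": d}
            for (a, s, d) in _sample_index(config)
        ]
    )
    return SyntheticDataset(config, community, truth, courses, meta)


def timecourses_to_frame(courses: list[DigestionTimeCourse]) -> pd.DataFrame:
    rows = []
    for tc in courses:
        for t, dpct in zip(tc.times_h, tc.digested_pct):
            rows.append(
                {
                    "animal": tc.key.animal,
                    "season": tc.key.season,
                    "diet": tc.key.diet,
                    "substrate": tc.key.substrate,
                    "fraction": tc.key.fraction,
                    "time_h": t,
                    "fraction_digested_pct": dpct,
                }
            )
    return pd.DataFrame.from_records(rows)


def write_dataset(
    dataset: SyntheticDataset, directory, overwrite: bool = False
) -> dict:
    """Write TSV/CSV artifacts and a JSON manifest; return the manifest.

    Values are written with full float repr so re-reading round-trips
    exactly.  Refuses to clobber an existing manifest unless ``overwrite``.
    """
    if not dataset.timecourses or dataset.community.data.empty:
        raise SimError("refusing to write an empty dataset")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise SimError(f"{manifest_path} exists; pass overwrite=True")

    from .community import write_taxon_table

    files = {}

    taxon_path = directory / "taxon_table.tsv"
    write_taxon_table(dataset.community, taxon_path)
    files["taxon_table.tsv"] = len(dataset.community.data.columns)

    tc = timecourses_to_frame(dataset.timecourses)
    tc_path = directory / "timecourses.csv"
    tc.to_csv(tc_path, index=False)
    files["timecourses.csv"] = len(tc)

    meta_path = directory / "metadata.csv"
    dataset.metadata.to_csv(meta_path, index=False)
    files["metadata.csv"] = len(dataset.metadata)

    gt_units = directory / "ground_truth_units.csv"
    dataset.truth.unit_params.to_csv(gt_units, index=False)
    files["ground_truth_units.csv"] = len(dataset.truth.unit_params)

    gt_gen = pd.DataFrame(
        {
            "genus": list(dataset.truth.gamma),
            "gamma_rate": list(dataset.truth.gamma.values()),
            "gamma_extent": [
                dataset.truth.gamma_extent[g] for g in dataset.truth.gamma
            ],
            "planted": [
                g in dataset.truth.planted_genus_ids for g in dataset.truth.gamma
            ],
        }
    )
    gt_gen_path = directory / "ground_truth_genera.csv"
    gt_gen.to_csv(gt_gen_path, index=False)
    files["ground_truth_genera.csv"] = len(gt_gen)

    manifest = {
        "seed": dataset.config.seed,
        "n_samples": dataset.config.n_samples,
        "files": files,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    for key in ("seasons", "diets", "substrates", "times_h", "effect_sizes",
                "extent_effect_sizes"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    if "base_params" in d:
        d["base_params"] = {k: tuple(v) for k, v in d["base_params"].items()}
    return SimConfig(**d)
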