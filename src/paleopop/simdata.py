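"""Synthetic pseudo-haploid datasets with known truth.

The generator reproduces the statistical structure the downstream analyses
assume — populations diverging from a shared ancestor (Balding-Nichols
drift), admixed groups formed as exact frequency mixtures of derived
sources, planted pedigrees transmitted by gene dropping (with hemizygous-X
rules), and a pseudo-haploid observation layer (one sampled allele per
site, symmetric allele-flip errors, per-individual missingness).

SNPs are transmitted independently (no linkage map): the statistics served
here are LD-agnostic, but every SNP still carries a physical position
(uniform over configurable chromosome lengths, sorted) because kinship
windows and jackknife blocks are defined physically.  Ancestral frequencies
are uniform on (0.05, 0.95) by default, so every SNP is polymorphic —
mirroring a common-variant (MAF > 10%) panel philosophy.

The default world has an outgroup on a long branch (F = 0.5), three sources
(F = 0.05-0.1) and a target admixed 0.48/0.33/0.19 across the sources,
echoing a three-way east-west admixture cline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pedx
from .genio import MISSING, GenotypeMatrix, write_eigenstrat

DEFAULT_CHROMOSOMES = tuple((str(i), 100_000_000) for i in range(1, 21))


@dataclass
class PopulationSpec:
    """One population: Balding-Nichols drift F from its base frequencies.

    ``admixture_of`` (list of (source name, weight)) makes the base an exact
    mixture of already-derived sources instead of the ancestral vector;
    drift, if nonzero, applies on top.
    """

    name: str
    drift: float = 0.0
    admixture_of: list[tuple[str, float]] | None = None
    n_samples: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drift < 1.0:
            raise ValueError(f"{self.name}: drift must be in [0, 1)")
        if self.n_samples < 0:
            raise ValueError(f"{self.name}: negative n_samples")
        if self.admixture_of is not None:
            w = np.array([w for _, w in self.admixture_of], dtype=float)
            if (w <= 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.name}: admixture weights must be positive and sum to 1"
                )


@dataclass
class PedigreeSpec:
    """A pedigree to plant: members (id, sex, father, mother), drawn from one population."""

    members: list[tuple[str, str, str | None, str | None]]
    population: str
    planted_relationships: list[tuple[str, str, str]] = field(default_factory=list)

    def to_pedigree(self) -> pedx.Pedigree:
        ped = pedx.Pedigree()
        for mid, sex, father, mother in self.members:
            ped.add(mid, sex, father, mother)
        ped.validate()
        return ped


@dataclass
class SimConfig:
    n_snps: int = 20_000
    chromosomes: tuple = DEFAULT_CHROMOSOMES
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    missingness: float | dict = 1.0  # callable fraction per individual
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral frequency bounds must satisfy 0 < low < high < 1")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


# ---------------------------------------------------------------------------
# frequency and genotype machinery
# ---------------------------------------------------------------------------

def derive_population_freqs(
    ancestral: np.ndarray,
    spec: PopulationSpec,
    rng: int | np.random.Generator,
    derived: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-SNP allele frequencies for one population.

    Unadmixed populations draw each SNP from the Balding-Nichols
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral p; admixed populations
    take the exact weighted mixture of already-derived source vectors (drift,
    if any, applies on top).  Values are clamped to [1e-6, 1 - 1e-6].
    """
    rng = np.random.default_rng(rng)
    ancestral = np.asarray(ancestral, dtype=float)
    if ((ancestral <= 0) | (ancestral >= 1)).any():
        raise ValueError("ancestral frequencies must lie in (0, 1)")
    if spec.admixture_of is not None:
        derived = derived or {}
        base = np.zeros_like(ancestral)
        for src, w in spec.admixture_of:
            if src not in derived:
                raise ValueError(f"{spec.name}: admixture source {src!r} not yet derived")
            base = base + w * derived[src]
    else:
        base = ancestral
    if spec.drift == 0.0:
        out = base.copy()
    else:
        f = spec.drift
        out = rng.beta(base * (1 - f) / f, (1 - base) * (1 - f) / f)
    return np.clip(out, 1e-6, 1 - 1e-6)


def _snp_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    names = [c for c, _ in config.chromosomes]
    lengths = np.array([l for _, l in config.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(names), size=config.n_snps, p=probs)
    pos = np.empty(config.n_snps, dtype=np.int64)
    for k, (name, length) in enumerate(config.chromosomes):
        mask = chrom_idx == k
        pos[mask] = np.sort(rng.choice(length, size=mask.sum(), replace=False)) + 1
    order = np.lexsort((pos, chrom_idx))
    chrom_idx, pos = chrom_idx[order], pos[order]
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(config.n_snps)],
            "chrom": [names[k] for k in chrom_idx],
            "gen_pos": 0.0,
            "pos": pos,
            "allele1": "A",
            "allele2": "G",
        }
    )


def sample_diploid(
    freqs: np.ndarray,
    n: int,
    rng: np.random.Generator,
    sexes: np.ndarray | None = None,
    x_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Hardy-Weinberg genotypes (allele1 copy counts); male X is hemizygous 0/2."""
    calls = rng.binomial(2, freqs[None, :], size=(n, len(freqs))).astype(np.int8)
    if sexes is not None and x_mask is not None and x_mask.any():
        male = np.asarray(sexes) == "M"
        if male.any():
            hemi = rng.binomial(1, freqs[x_mask][None, :], size=(male.sum(), x_mask.sum()))
            calls[np.ix_(male, x_mask)] = (2 * hemi).astype(np.int8)
    return calls


def gene_drop_pedigree(
    ped_spec: PedigreeSpec,
    founder_freqs: np.ndarray,
    snps: pd.DataFrame,
    rng: int | np.random.Generator,
) -> tuple[list[str], np.ndarray]:
    """Diploid genotypes for a pedigree by per-SNP Mendelian transmission.

    Founders draw alleles from the population frequencies under
    Hardy-Weinberg; each parent passes one of its two alleles uniformly and
    independently per SNP.  On the X, mothers pass one of two alleles,
    fathers pass their single X to daughters only; male X calls are
    hemizygous, encoded 0/2.  Identical-twin members can be planted by
    giving two ids the same parents and copying is left to the caller via
    ``planted_relationships`` handling in :func:`simulate_world`.
    """
    rng = np.random.default_rng(rng)
    ped = ped_spec.to_pedigree()
    order = ped.topological_order()
    n_snps = len(snps)
    x_mask = np.isin(snps["chrom"].to_numpy(dtype=object), ["X", "23", "chrX"])
    auto = {}
    xall = {}
    for mid in order:
        sex, father, mother = ped.members[mid]
        if father is None:
            auto[mid] = rng.binomial(1, founder_freqs, size=(2, n_snps)).astype(np.int8)
            if sex == "F":
                xall[mid] = rng.binomial(1, founder_freqs, size=(2, n_snps)).astype(np.int8)
            else:
                xall[mid] = rng.binomial(1, founder_freqs, size=(1, n_snps)).astype(np.int8)
        else:
            pick_f = rng.integers(2, size=n_snps)
            pick_m = rng.integers(2, size=n_snps)
            idx = np.arange(n_snps)
            auto[mid] = np.stack(
                [auto[father][pick_f, idx], auto[mother][pick_m, idx]]
            ).astype(np.int8)
            kx = xall[mother].shape[0]
            pick_x = rng.integers(kx, size=n_snps)
            from_mother = xall[mother][pick_x, idx]
            if sex == "M":
                xall[mid] = from_mother[None, :].astype(np.int8)
            else:
                xall[mid] = np.stack([xall[father][0], from_mother]).astype(np.int8)
    ids, calls = [], []
    for mid in order:
        sex = ped.sex(mid)
        row = auto[mid].sum(axis=0)
        if x_mask.any():
            if sex == "M":
                row = row.copy()
                row[x_mask] = 2 * xall[mid][0, x_mask]
            else:
                row = row.copy()
                row[x_mask] = xall[mid][:, x_mask].sum(axis=0)
        ids.append(mid)
        calls.append(row)
    return ids, np.array(calls, dtype=np.int8)


def pseudo_haploidize(
    matrix: GenotypeMatrix,
    missingness: float | dict = 1.0,
    error_rate: float = 0.0,
    rng: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Sample one allele per called site, add flip errors and missingness.

    Heterozygous sites pick either allele with probability 1/2; the chosen
    allele is flipped with probability ``error_rate`` and encoded as a
    homozygous 0/2 call.  Each site is independently retained with the
    individual's callable fraction (``missingness`` may be a scalar or an
    id -> fraction mapping); fully missing individuals are legal but logged.
    """
    rng = np.random.default_rng(rng)
    calls = matrix.calls
    miss = calls == MISSING
    # chosen allele: hom 0 -> 0, hom 2 -> 1, het -> coin flip
    allele = (calls == 2).astype(np.int8)
    het = calls == 1
    allele[het] = rng.integers(2, size=int(het.sum()))
    if error_rate > 0:
        flips = rng.random(calls.shape) < error_rate
        allele = np.where(flips, 1 - allele, allele)
    out = (2 * allele).astype(np.int8)
    if isinstance(missingness, dict):
        keep_p = np.array([missingness[i] for i in matrix.individuals])[:, None]
    else:
        keep_p = np.full((matrix.n_individuals, 1), float(missingness))
    drop = rng.random(calls.shape) >= keep_p
    out[miss | drop] = MISSING
    if (out == MISSING).all(axis=1).any():
        logging.getLogger(__name__).warning("pseudo_haploidize: all-missing individual")
    return GenotypeMatrix(
        snps=matrix.snps,
        individuals=list(matrix.individuals),
        calls=out,
        pseudo_haploid=np.ones(matrix.n_individuals, dtype=bool),
        sex=matrix.sex,
        par_mask=matrix.par_mask,
    )


# ---------------------------------------------------------------------------
# whole-world simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedWorld:
    matrix: GenotypeMatrix  # pseudo-haploid observation
    diploid: GenotypeMatrix  # underlying truth genotypes
    freqs: dict[str, np.ndarray]
    truth: dict
    meta: pd.DataFrame


def default_world_specs() -> list[PopulationSpec]:
    """Outgroup + three drifted sources + one three-way admixed target."""
    return [
        PopulationSpec("outgroup", drift=0.5, n_samples=5),
        PopulationSpec("west", drift=0.05, n_samples=5),
        PopulationSpec("central", drift=0.075, n_samples=5),
        PopulationSpec("east", drift=0.1, n_samples=5),
        PopulationSpec(
            "target",
            drift=0.0,
            admixture_of=[("west", 0.48), ("central", 0.33), ("east", 0.19)],
            n_samples=5,
        ),
    ]


def admixture_study_specs(
    weights: list[float],
    n_samples: int = 8,
    shared_drift: float = 0.1,
    tip_drift: float = 0.05,
    target_samples: int = 8,
) -> tuple[list[PopulationSpec], list[str], list[str], str]:
    """Population design for admixture-weight estimation studies.

    Each source ``s{i}`` shares a drifted internal branch with a sister
    reference ``r{i}``, so the references are differentially related to the
    sources (the condition qpAdm-style fitting needs); an outgroup and one
    extra independent reference complete the right set.  Returns
    (specs, sources, right, target).
    """
    k = len(weights)
    specs = [PopulationSpec("outgroup", drift=0.5, n_samples=n_samples)]
    sources, right = [], ["outgroup"]
    for i in range(k):
        anc = f"anc{i}"
        specs.append(PopulationSpec(anc, drift=shared_drift, n_samples=0))
        specs.append(PopulationSpec(
            f"s{i}", drift=tip_drift, admixture_of=[(anc, 1.0)], n_samples=n_samples))
        specs.append(PopulationSpec(
            f"r{i}", drift=tip_drift, admixture_of=[(anc, 1.0)], n_samples=n_samples))
        sources.append(f"s{i}")
        right.append(f"r{i}")
    specs.append(PopulationSpec("r_extra", drift=0.15, n_samples=n_samples))
    right.append("r_extra")
    specs.append(PopulationSpec(
        "target",
        admixture_of=[(f"s{i}", w) for i, w in enumerate(weights)],
        n_samples=target_samples,
    ))
    return specs, sources, right, "target"


def simulate_world(
    pop_specs: list[PopulationSpec],
    config: SimConfig,
    pedigrees: list[PedigreeSpec] = (),
    identical_twins: list[tuple[str, str]] = (),
    meta_plan: dict[str, dict] | None = None,
) -> SimulatedWorld:
    """Simulate a full dataset: frequencies, genotypes, pedigrees, observation.

    ``identical_twins`` lists (existing id, duplicate id) pairs: the
    duplicate receives the same underlying diploid genome and is then
    pseudo-haploidized independently (the identical-pair scenario).
    ``meta_plan`` maps population name to site metadata (site, lat, lon,
    date_mean, date_sd, buildings) used to fill the sample table.
    """
    rng = np.random.default_rng(config.seed)
    snps = _snp_table(config, rng)
    lo, hi = config.ancestral_freq_range
    ancestral = rng.uniform(lo, hi, size=config.n_snps)
    x_mask = np.isin(snps["chrom"].to_numpy(dtype=object), ["X", "23", "chrX"])

    freqs: dict[str, np.ndarray] = {}
    for spec in pop_specs:
        freqs[spec.name] = derive_population_freqs(ancestral, spec, rng, freqs)

    ids: list[str] = []
    calls_rows: list[np.ndarray] = []
    sexes: list[str] = []
    pop_of: dict[str, str] = {}
    for spec in pop_specs:
        if spec.n_samples == 0:
            continue
        sx = np.array(["F" if i % 2 == 0 else "M" for i in range(spec.n_samples)])
        g = sample_diploid(freqs[spec.name], spec.n_samples, rng, sx, x_mask)
        for i in range(spec.n_samples):
            ind = f"{spec.name}_{i}"
            ids.append(ind)
            sexes.append(sx[i])
            pop_of[ind] = spec.name
        calls_rows.append(g)

    truth_relations = []
    for ped_spec in pedigrees:
        pids, pcalls = gene_drop_pedigree(ped_spec, freqs[ped_spec.population], snps, rng)
        ped = ped_spec.to_pedigree()
        for mid in pids:
            ids.append(mid)
            sexes.append(ped.sex(mid))
            pop_of[mid] = ped_spec.population
        calls_rows.append(pcalls)
        for a, b, relation in ped_spec.planted_relationships:
            truth_relations.append(
                {
                    "id1": a,
                    "id2": b,
                    "relation": relation,
                    "theta_auto": pedx.kinship_auto(ped, a, b),
                    "theta_x": pedx.kinship_x(ped, a, b),
                }
            )
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate individual ids across populations/pedigrees")

    calls = np.vstack(calls_rows) if calls_rows else np.empty((0, config.n_snps), np.int8)
    sexes_arr = np.array(sexes)

    for src, dup in identical_twins:
        if dup in ids:
            raise ValueError(f"duplicate individual id {dup!r}")
        i = ids.index(src)
        ids.append(dup)
        calls = np.vstack([calls, calls[i][None, :]])
        sexes_arr = np.append(sexes_arr, sexes_arr[i])
        pop_of[dup] = pop_of[src]
        truth_relations.append(
            {"id1": src, "id2": dup, "relation": "identical",
             "theta_auto": 0.5, "theta_x": 0.5 if sexes_arr[i] == "F" else 1.0}
        )

    diploid = GenotypeMatrix(
        snps=snps,
        individuals=ids,
        calls=calls,
        pseudo_haploid=np.zeros(len(ids), dtype=bool),
        sex=sexes_arr,
    )
    observed = pseudo_haploidize(diploid, config.missingness, config.error_rate, rng)

    meta_plan = meta_plan or {}
    meta_rows = []
    for ind in ids:
        plan = meta_plan.get(pop_of[ind], {})
        buildings = plan.get("buildings")
        meta_rows.append(
            {
                "id": ind,
                "population": pop_of[ind],
                "site": plan.get("site", pop_of[ind]),
                "building": buildings[len(meta_rows) % len(buildings)] if buildings else None,
                "sex": sexes_arr[list(ids).index(ind)],
                "lat": plan.get("lat", 0.0),
                "lon": plan.get("lon", 0.0),
                "date_mean": plan.get("date_mean", 8000.0),
                "date_sd": plan.get("date_sd", 100.0),
            }
        )
    meta = pd.DataFrame(meta_rows)

    ancestry = {}
    for ind in ids:
        spec = next(s for s in pop_specs if s.name == pop_of[ind])
        if spec.admixture_of:
            ancestry[ind] = {src: w for src, w in spec.admixture_of}
        else:
            ancestry[ind] = {spec.name: 1.0}
    truth = {
        "seed": config.seed,
        "ancestry": ancestry,
        "relations": truth_relations,
        "sex": {i: s for i, s in zip(ids, sexes_arr)},
    }
    return SimulatedWorld(observed, diploid, freqs, truth, meta)


# ---------------------------------------------------------------------------
# study-design presets
# ---------------------------------------------------------------------------

def kinship_study_world(
    seed: int,
    n_snps: int = 10_000,
    n_unrelated: int = 12,
    missingness: float = 1.0,
) -> tuple[SimulatedWorld, list[str]]:
    """One population with planted relative pairs of every degree.

    Plants an identical pair (duplicated genome, independently observed), a
    mother-daughter pair (1st degree), paternal half-siblings (2nd) and
    first cousins (3rd) among ``n_unrelated`` unrelated individuals.
    Returns the world plus the ids to analyze (non-focal pedigree members —
    parents, grandparents — are left out so the sample stays mostly
    unrelated, as the median-P0 baseline assumes).
    """
    peds = [
        PedigreeSpec(
            members=[("po_f", "M", None, None), ("po_m", "F", None, None),
                     ("po_c", "F", "po_f", "po_m")],
            population="pop",
            planted_relationships=[("po_m", "po_c", "first")],
        ),
        PedigreeSpec(
            members=[("hs_f", "M", None, None), ("hs_w1", "F", None, None),
                     ("hs_w2", "F", None, None),
                     ("hs_a", "F", "hs_f", "hs_w1"),
                     ("hs_b", "M", "hs_f", "hs_w2")],
            population="pop",
            planted_relationships=[("hs_a", "hs_b", "second")],
        ),
        PedigreeSpec(
            members=[("fc_gf", "M", None, None), ("fc_gm", "F", None, None),
                     ("fc_p1", "M", "fc_gf", "fc_gm"),
                     ("fc_p2", "F", "fc_gf", "fc_gm"),
                     ("fc_s1", "F", None, None), ("fc_s2", "M", None, None),
                     ("fc_a", "F", "fc_p1", "fc_s1"),
                     ("fc_b", "F", "fc_s2", "fc_p2")],
            population="pop",
            planted_relationships=[("fc_a", "fc_b", "third")],
        ),
    ]
    specs = [PopulationSpec("pop", drift=0.05, n_samples=n_unrelated)]
    cfg = SimConfig(n_snps=n_snps, seed=seed, missingness=missingness)
    world = simulate_world(specs, cfg, pedigrees=peds,
                           identical_twins=[("pop_0", "pop_0_twin")])
    focal = {"po_m", "po_c", "hs_a", "hs_b", "fc_a", "fc_b"}
    analysis_ids = [
        i for i in world.matrix.individuals
        if i.startswith("pop_") or i in focal
    ]
    return world, analysis_ids


def cline_world(
    seed: int,
    n_snps: int = 8_000,
    n_sites: int = 6,
    step_drift: float = 0.02,
    n_per_site: int = 4,
    with_drifted_branch: bool = False,
    branch_drift: float = 0.08,
) -> SimulatedWorld:
    """Stepping-stone cline: sites along a line, drift accumulating stepwise.

    Population i derives from population i-1 with drift ``step_drift`` and
    sits 2 degrees of longitude further east, so genetic dissimilarity grows
    with geographic distance (isolation by distance).  With
    ``with_drifted_branch`` an extra deep-lineage population sits in the
    middle of the cline geographically while branching directly off the
    ancestral root: sharing almost no drift with the chain, its pairs are
    more differentiated than distance predicts (outgroup-f3 dissimilarity
    responds to shared drift, not to a population's private drift).
    """
    specs = [PopulationSpec("outgroup", drift=0.5, n_samples=4)]
    plan = {"outgroup": dict(site="og", lat=50.0, lon=50.0, date_mean=8000.0)}
    prev = None
    for i in range(n_sites):
        name = f"p{i}"
        if prev is None:
            specs.append(PopulationSpec(name, drift=step_drift,
                                        n_samples=n_per_site))
        else:
            specs.append(PopulationSpec(name, drift=step_drift,
                                        admixture_of=[(prev, 1.0)],
                                        n_samples=n_per_site))
        plan[name] = dict(site=f"site{i}", lat=0.0, lon=float(2 * i),
                          date_mean=8000.0)
        prev = name
    if with_drifted_branch:
        specs.append(PopulationSpec("isolate", drift=branch_drift,
                                    n_samples=n_per_site))
        plan["isolate"] = dict(site="isolate_site", lat=1.0,
                               lon=float(2 * (n_sites // 2 - 1) + 1),
                               date_mean=8000.0)
    cfg = SimConfig(n_snps=n_snps, seed=seed)
    return simulate_world(specs, cfg, meta_plan=plan)


def family_buildings_world(
    seed: int,
    n_buildings: int = 4,
    n_snps: int = 6_000,
) -> tuple[SimulatedWorld, list[str], dict[str, str]]:
    """Buildings housing extended families (mutual second cousins).

    Each building holds four sampled individuals who are pairwise second
    cousins (kinship 1/64 — below the detection range of mismatch-rate
    kinship), descended from one great-grandparental couple.  Returns the
    world, the sampled ids and the id -> building map.
    """
    peds = []
    for b in range(n_buildings):
        members = [(f"b{b}_gg_f", "M", None, None),
                   (f"b{b}_gg_m", "F", None, None)]
        for line in range(4):
            child_sex = "F" if line % 2 == 0 else "M"
            members.append((f"b{b}_c{line}", child_sex,
                            f"b{b}_gg_f", f"b{b}_gg_m"))
            sp_sex = "M" if child_sex == "F" else "F"
            members.append((f"b{b}_c{line}_sp", sp_sex, None, None))
            fa = f"b{b}_c{line}" if child_sex == "M" else f"b{b}_c{line}_sp"
            mo = f"b{b}_c{line}_sp" if child_sex == "M" else f"b{b}_c{line}"
            members.append((f"b{b}_g{line}", "F", fa, mo))
            members.append((f"b{b}_g{line}_sp", "M", None, None))
            members.append((f"b{b}_s{line}", "F",
                            f"b{b}_g{line}_sp", f"b{b}_g{line}"))
        peds.append(PedigreeSpec(members=members, population="pop"))
    specs = [PopulationSpec("outgroup", drift=0.5, n_samples=4),
             PopulationSpec("pop", drift=0.05, n_samples=0)]
    plan = {"pop": dict(site="s", lat=0.0, lon=0.0, date_mean=8000.0),
            "outgroup": dict(site="og", lat=50.0, lon=50.0, date_mean=8000.0)}
    world = simulate_world(specs, SimConfig(n_snps=n_snps, seed=seed),
                           pedigrees=peds, meta_plan=plan)
    samples = [f"b{b}_s{l}" for b in range(n_buildings) for l in range(4)]
    buildings = {s: s.split("_")[0] for s in samples}
    return world, samples, buildings


def emit_dataset(world: SimulatedWorld, out_prefix) -> None:
    """Write the EIGENSTRAT trio, metadata TSV and truth JSON (deterministic)."""
    prefix = str(out_prefix)
    meta = world.meta.copy()
    ind = pd.DataFrame(
        {"id": meta["id"], "sex": meta["sex"], "population": meta["population"]}
    )
    write_eigenstrat(world.matrix, prefix, ind)
    meta.to_csv(prefix + ".meta.tsv", sep="\t", index=False)
    with open(prefix + ".truth.json", "w") as fh:
        json.dump(world.truth, fh, indent=1, sort_keys=True)
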