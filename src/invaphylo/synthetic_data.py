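"""Synthetic occurrence databases with known establishment ground truth.

The generator emulates the statistical structure the occurrence models
assume, not the geography of any real dataset:

1. a pure-birth (optionally birth–death) ultrametric phylogeny for the
   species pool;
2. a one-dimensional environmental-tolerance trait evolving on the tree by
   Brownian motion, so closely related species prefer similar environments;
3. basins nested in countries nested in realms, each basin carrying an
   environmental value (country optimum plus basin jitter);
4. native community assembly by Gaussian environmental filtering — species
   s is native in basin b with probability
   baseline × exp(−(trait_s − env_b)² / (2 τ²)) — which induces realistic
   covariation between native richness and nonnative–native relatedness;
5. proposed introductions of species into countries (exotic: no native
   basin in the country; translocated: at least one), each candidate basin
   then establishing with probability
   g⁻¹(β0 + β_rel · REL_z + β_rich · richness_z + u_species + u_country + u_basin),
   where REL is the nonnative–native MPD (or MNTD, by configuration)
   standardized over the proposal set, matching the convention of the
   record builder so the programmed coefficients are recoverable on the
   same scale.

Every stage draws from its own child generator split off the master seed,
so changing one stage's parameters does not perturb another stage's draws.
The full configuration, the realized random intercepts, and the per-record
establishment probabilities are returned as :class:`SimulationTruth`.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .occurrence_db import NATIVE, NONNATIVE, OccurrenceDatabase
from .phylometrics import DistanceMatrix, cophenetic_distances

_REALM_NAMES = [
    "Palearctic",
    "Nearctic",
    "Neotropic",
    "Afrotropic",
    "Indo-Malay",
    "Australasia",
    "Oceania",
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study system (defaults are the study
    conditions used throughout the test suite)."""

    n_species: int = 100
    n_realms: int = 3
    countries_per_realm: int = 2
    basins_per_country: int = 8
    birth_rate: float = 1.0
    death_rate: float = 0.0
    bm_sigma2: float = 1.0  # Brownian motion rate of the tolerance trait
    filter_tau: float = 2.0  # width of the Gaussian environmental filter
    baseline_occupancy: float = 0.35  # occupancy at perfect trait-env match
    beta0: float = -1.0  # establishment intercept (logit scale)
    beta_relatedness: float = -0.5  # slope on the z-scored relatedness metric
    beta_richness: float = 0.3  # slope on z-scored native richness
    sd_species: float = 0.5
    sd_country: float = 0.3
    sd_basin: float = 0.3
    introduction_rate: float = 0.3  # fraction of eligible species-country pairs
    relatedness_metric: str = "mpd"  # generative driver: 'mpd' or 'mntd'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not 1 <= self.n_realms <= len(_REALM_NAMES):
            raise ValueError(f"n_realms must be in 1..{len(_REALM_NAMES)}")
        if min(self.countries_per_realm, self.basins_per_country) < 1:
            raise ValueError("counts must be >= 1")
        if self.relatedness_metric not in ("mpd", "mntd"):
            raise ValueError("relatedness_metric must be 'mpd' or 'mntd'")
        for name in ("birth_rate", "bm_sigma2", "filter_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SimulationTruth:
    """Everything needed to check parameter recovery downstream."""

    config: GeneratorConfig
    traits: dict[str, float]
    basin_env: dict[str, float]
    u_species: dict[str, float]
    u_country: dict[str, float]
    u_basin: dict[str, float]
    proposals: pd.DataFrame = field(repr=False)

    def to_manifest(self) -> dict:
        return {
            "config": asdict(self.config),
            "n_proposals": int(len(self.proposals)),
            "n_established": int(self.proposals["established"].sum()),
        }


def simulate_tree(
    n_species: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
) -> dendropy.Tree:
    """Seeded ultrametric birth–death tree with ``n_species`` extant tips.

    Tips are relabelled ``S0001``..; with extinction, the simulation retries
    a bounded number of times before raising.
    """
    from dendropy.simulate import treesim

    if n_species < 2:
        raise ValueError("need at least 2 tips")
    last_err: Exception | None = None
    for attempt in range(20):
        rng = random.Random((seed + 1_000_003 * attempt) % 2**31)
        try:
            tree = treesim.birth_death_tree(
                birth_rate=birth_rate,
                death_rate=death_rate,
                num_extant_tips=n_species,
                rng=rng,
            )
        except Exception as err:  # all-lineages-extinct runs
            last_err = err
            continue
        width = max(4, len(str(n_species)))
        for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
            leaf.taxon.label = f"S{i:0{width}d}"
        return tree
    raise RuntimeError(
        f"birth-death simulation failed after 20 attempts "
        f"(birth={birth_rate}, death={death_rate}): {last_err}"
    )


def brownian_traits(
    tree: dendropy.Tree, sigma2: float, rng: np.random.Generator
) -> dict[str, float]:
    """Evolve a 1-D trait along the tree: child = parent + N(0, σ²·branch)."""
    values: dict = {}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = 0.0
        else:
            bl = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(
                0.0, math.sqrt(sigma2 * bl)
            )
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return out


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def simulate_database(
    config: GeneratorConfig,
) -> tuple[OccurrenceDatabase, dendropy.Tree, SimulationTruth]:
    """Generate a database, its phylogeny, and the full simulation truth."""
    master = np.random.SeedSequence(config.seed)
    s_tree, s_trait, s_assembly, s_intro = master.spawn(4)

    tree = simulate_tree(
        config.n_species,
        config.birth_rate,
        config.death_rate,
        seed=int(s_tree.generate_state(1)[0] % 2**31),
    )
    rng_trait = np.random.default_rng(s_trait)
    traits = brownian_traits(tree, config.bm_sigma2, rng_trait)
    species = sorted(traits)
    trait_arr = np.array([traits[s] for s in species])
    # center the trait so the filter is anchored at the community mean
    trait_arr = trait_arr - trait_arr.mean()
    traits = dict(zip(species, trait_arr))

    # --- geography -------------------------------------------------------
    rng_asm = np.random.default_rng(s_assembly)
    realms = _REALM_NAMES[: config.n_realms]
    basin_rows = []
    basin_env: dict[str, float] = {}
    countries: list[str] = []
    for ri, realm in enumerate(realms):
        for ci in range(config.countries_per_realm):
            country = f"C{ri * config.countries_per_realm + ci + 1:02d}"
            countries.append(country)
            optimum = rng_asm.normal(0.0, 1.0)
            for bi in range(config.basins_per_country):
                basin = f"{country}_b{bi + 1:02d}"
                env = optimum + rng_asm.normal(0.0, 0.5)
                basin_env[basin] = env
                basin_rows.append(
                    {
                        "basin_id": basin,
                        "country": country,
                        "realm": realm,
                        "area_km2": float(np.exp(rng_asm.normal(8.0, 1.5))),
                        "lat": float(rng_asm.uniform(-60.0, 70.0)),
                        "lon": float(rng_asm.uniform(-180.0, 180.0)),
                    }
                )
    basins = pd.DataFrame(basin_rows).set_index("basin_id")

    # --- native assembly by environmental filtering ----------------------
    basin_ids = list(basins.index)
    env_arr = np.array([basin_env[b] for b in basin_ids])
    match = np.exp(
        -((trait_arr[:, None] - env_arr[None, :]) ** 2)
        / (2.0 * config.filter_tau**2)
    )
    occ_prob = config.baseline_occupancy * match
    native_mask = rng_asm.random(occ_prob.shape) < occ_prob
    if not native_mask.any():
        raise ValueError("configuration produced zero native records")

    native_basins_of = {
        s: {basin_ids[j] for j in np.flatnonzero(native_mask[i])}
        for i, s in enumerate(species)
    }
    native_countries_of = {
        s: {basins.at[b, "country"] for b in bs}
        for s, bs in native_basins_of.items()
    }

    # --- proposed introductions ------------------------------------------
    rng_intro = np.random.default_rng(s_intro)
    D = cophenetic_distances(tree)
    natives_by_basin = {
        b: [species[i] for i in np.flatnonzero(native_mask[:, j])]
        for j, b in enumerate(basin_ids)
    }
    basins_by_country: dict[str, list[str]] = {}
    for b in basin_ids:
        basins_by_country.setdefault(basins.at[b, "country"], []).append(b)

    prop_rows = []
    for s in species:
        for country in countries:
            is_native_here = country in native_countries_of[s]
            group = "translocated" if is_native_here else "exotic"
            if rng_intro.random() >= config.introduction_rate:
                continue
            for b in basins_by_country[country]:
                if b in native_basins_of[s]:
                    continue  # never introduce into an origin basin
                natives = [n for n in natives_by_basin[b] if n != s]
                if not natives:
                    continue
                row = D.values[D.indices([s])[0], D.indices(natives)]
                rel = float(row.mean()) if config.relatedness_metric == "mpd" else float(row.min())
                prop_rows.append(
                    {
                        "species": s,
                        "basin_id": b,
                        "country": country,
                        "group": group,
                        "relatedness": rel,
                        "native_richness": len(natives),
                    }
                )
    proposals = pd.DataFrame(
        prop_rows,
        columns=[
            "species",
            "basin_id",
            "country",
            "group",
            "relatedness",
            "native_richness",
        ],
    )
    if proposals.empty:
        proposals = proposals.assign(
            relatedness_z=[], richness_z=[], eta=[], prob=[], established=[]
        )
        established = proposals
    else:
        rel = proposals["relatedness"].to_numpy()
        rich = proposals["native_richness"].to_numpy(dtype=float)
        rel_z = (rel - rel.mean()) / rel.std(ddof=1) if rel.std(ddof=1) > 0 else rel * 0
        rich_z = (
            (rich - rich.mean()) / rich.std(ddof=1) if rich.std(ddof=1) > 0 else rich * 0
        )
        u_sp = {s: rng_intro.normal(0.0, config.sd_species) for s in species}
        u_co = {c: rng_intro.normal(0.0, config.sd_country) for c in countries}
        u_ba = {b: rng_intro.normal(0.0, config.sd_basin) for b in basin_ids}
        eta = (
            config.beta0
            + config.beta_relatedness * rel_z
            + config.beta_richness * rich_z
            + np.array([u_sp[s] for s in proposals["species"]])
            + np.array([u_co[c] for c in proposals["country"]])
            + np.array([u_ba[b] for b in proposals["basin_id"]])
        )
        prob = _inv_logit(eta)
        est = rng_intro.random(len(proposals)) < prob
        proposals = proposals.assign(
            relatedness_z=rel_z,
            richness_z=rich_z,
            eta=eta,
            prob=prob,
            established=est,
        )
        established = proposals[proposals["established"]]

    # --- assemble the database -------------------------------------------
    rec_rows = [
        {"species": s, "basin_id": b, "status": NATIVE}
        for s in species
        for b in sorted(native_basins_of[s])
    ]
    for sp, b in established[["species", "basin_id"]].itertuples(index=False):
        rec_rows.append({"species": sp, "basin_id": b, "status": NONNATIVE})
    records = pd.DataFrame(rec_rows, columns=["species", "basin_id", "status"])
    db = OccurrenceDatabase(basins=basins, records=records)

    if proposals.empty:
        u_sp, u_co, u_ba = {}, {}, {}
    truth = SimulationTruth(
        config=config,
        traits=traits,
        basin_env=basin_env,
        u_species={k: float(v) for k, v in u_sp.items()},
        u_country={k: float(v) for k, v in u_co.items()},
        u_basin={k: float(v) for k, v in u_ba.items()},
        proposals=proposals,
    )
    return db, tree, truth


# --------------------------------------------------------------------------
# direct model-level simulators (no geography): used to validate the
# estimation machinery against known coefficients without the selection
# effects of community assembly


def simulate_glmm_records(
    seed: int,
    beta: dict[str, float] | None = None,
    n_species: int = 100,
    n_countries: int = 5,
    basins_per_country: int = 10,
    sd_species: float = 0.5,
    sd_country: float = 0.3,
    sd_basin: float = 0.3,
) -> pd.DataFrame:
    """Draw records directly from the Bernoulli mixed model.

    Every species is paired with every basin; the single continuous
    predictor ``mpd_z`` is standard normal.  Columns match the modeling
    table (presence, mpd_z, species, country, basin_id), so the result can
    be passed straight to the occurrence-model fitters.
    """
    beta = {"(Intercept)": -1.0, "mpd_z": -0.5} | (beta or {})
    rng = np.random.default_rng(seed)
    n_basins = n_countries * basins_per_country
    u_s = rng.normal(0.0, sd_species, n_species)
    u_c = rng.normal(0.0, sd_country, n_countries)
    u_b = rng.normal(0.0, sd_basin, n_basins)
    sp = np.repeat(np.arange(n_species), n_basins)
    ba = np.tile(np.arange(n_basins), n_species)
    co = ba // basins_per_country
    x = rng.normal(size=n_species * n_basins)
    eta = beta["(Intercept)"] + beta["mpd_z"] * x + u_s[sp] + u_c[co] + u_b[ba]
    y = (rng.random(len(eta)) < _inv_logit(eta)).astype(int)
    return pd.DataFrame(
        {
            "presence": y,
            "mpd_z": x,
            "species": [f"S{i:04d}" for i in sp],
            "country": [f"C{i:02d}" for i in co],
            "basin_id": [f"B{i:03d}" for i in ba],
        }
    )


def simulate_sem_records(
    seed: int,
    path_richness_rel: float = -0.4,
    path_div_rel: float = 0.3,
    path_rel_presence: float = -0.6,
    path_richness_presence: float = 0.2,
    path_div_presence: float = 0.1,
    intercept: float = -0.5,
    n_species: int = 40,
    n_countries: int = 6,
    basins_per_country: int = 5,
    sd_species: float = 0.4,
    sd_country: float = 0.2,
    sd_basin: float = 0.2,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Draw records from the path model predictors → relatedness → presence.

    Basin-level richness and native diversity are standard normal;
    record-level relatedness is their linear combination plus noise scaled
    so the marginal variance is 1 (paths are therefore standardized).
    Presence follows a logit Bernoulli model with species/country/basin
    random intercepts.  Returns the table and the programmed truth,
    including each indirect effect (product of paths through relatedness).
    """
    a1, a2 = path_richness_rel, path_div_rel
    if a1 * a1 + a2 * a2 >= 1.0:
        raise ValueError("paths into relatedness imply variance > 1")
    rng = np.random.default_rng(seed)
    n_basins = n_countries * basins_per_country
    rich_b = rng.normal(size=n_basins)
    div_b = rng.normal(size=n_basins)
    sp = np.repeat(np.arange(n_species), n_basins)
    ba = np.tile(np.arange(n_basins), n_species)
    co = ba // basins_per_country
    eps_sd = math.sqrt(1.0 - a1 * a1 - a2 * a2)
    rel = a1 * rich_b[ba] + a2 * div_b[ba] + rng.normal(0.0, eps_sd, len(ba))
    u_s = rng.normal(0.0, sd_species, n_species)
    u_c = rng.normal(0.0, sd_country, n_countries)
    u_b = rng.normal(0.0, sd_basin, n_basins)
    eta = (
        intercept
        + path_rel_presence * rel
        + path_richness_presence * rich_b[ba]
        + path_div_presence * div_b[ba]
        + u_s[sp]
        + u_c[co]
        + u_b[ba]
    )
    y = (rng.random(len(eta)) < _inv_logit(eta)).astype(int)
    table = pd.DataFrame(
        {
            "presence": y,
            "mpd_z": rel,
            "native_richness_z": rich_b[ba],
            "native_mpd_z": div_b[ba],
            "species": [f"S{i:04d}" for i in sp],
            "country": [f"C{i:02d}" for i in co],
            "basin_id": [f"B{i:03d}" for i in ba],
        }
    )
    truth = {
        "path_richness_rel": a1,
        "path_div_rel": a2,
        "path_rel_presence": path_rel_presence,
        "indirect_richness": a1 * path_rel_presence,
        "indirect_div": a2 * path_rel_presence,
    }
    return table, truth


# --------------------------------------------------------------------------
# hand-auditable fixtures

FIXTURES = ("tiny", "toy-country", "realm-scope", "single-native-basin")

_TINY_TREE = "((A:1,B:1):1,C:2);"


def _fixture_frames(name: str):
    if name == "tiny":
        # worked 3-tip tree; A translocated within X, C exotic to X
        basins = [
            ("b1", "X", "Palearctic", 100.0, 10.0, 10.0),
            ("b2", "X", "Palearctic", 200.0, 11.0, 11.0),
        ]
        records = [
            ("A", "b1", NATIVE),
            ("A", "b2", NONNATIVE),
            ("B", "b2", NATIVE),
            ("C", "b1", NONNATIVE),
        ]
        tree = _TINY_TREE
    elif name == "toy-country":
        # one country, three basins; E exotic in b1, T translocated b1 -> b2
        basins = [
            ("b1", "X", "Palearctic", 100.0, 10.0, 10.0),
            ("b2", "X", "Palearctic", 200.0, 11.0, 11.0),
            ("b3", "X", "Palearctic", 300.0, 12.0, 12.0),
        ]
        records = [
            ("N1", "b1", NATIVE),
            ("T", "b1", NATIVE),
            ("N2", "b2", NATIVE),
            ("N3", "b3", NATIVE),
            ("E", "b1", NONNATIVE),
            ("T", "b2", NONNATIVE),
        ]
        tree = "(((N1:1,E:1):1,N2:2):1,(N3:1,T:1):2);"
    elif name == "realm-scope":
        # S native in Y, non-native in X; X and Y share a realm, Z does not
        basins = [
            ("x1", "X", "Palearctic", 100.0, 10.0, 10.0),
            ("y1", "Y", "Palearctic", 200.0, 20.0, 20.0),
            ("z1", "Z", "Nearctic", 300.0, 40.0, -100.0),
        ]
        records = [
            ("S", "y1", NATIVE),
            ("S", "x1", NONNATIVE),
            ("S", "z1", NONNATIVE),
            ("M", "x1", NATIVE),
            ("Q", "z1", NATIVE),
        ]
        tree = "((S:1,M:1):1,Q:2);"
    elif name == "single-native-basin":
        # basin b2 has exactly one native: native MPD/MNTD undefined there
        basins = [
            ("b1", "X", "Palearctic", 100.0, 10.0, 10.0),
            ("b2", "X", "Palearctic", 200.0, 11.0, 11.0),
        ]
        records = [
            ("A", "b1", NATIVE),
            ("B", "b1", NATIVE),
            ("B", "b2", NATIVE),
            ("C", "b1", NONNATIVE),
            ("C", "b2", NONNATIVE),
        ]
        tree = _TINY_TREE
    else:
        raise KeyError(
            f"unknown fixture {name!r}; available fixtures: {', '.join(FIXTURES)}"
        )
    occ = pd.DataFrame(records, columns=["species", "basin_id", "status"])
    bas = pd.DataFrame(
        basins, columns=["basin_id", "country", "realm", "area_km2", "lat", "lon"]
    )
    return occ, bas, tree


def make_fixture(name: str, outdir: str | Path) -> dict[str, Path]:
    """Write a named hand-auditable fixture (occurrences, basins, Newick)."""
    occ, bas, tree = _fixture_frames(name)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrences": outdir / f"{name}-occurrences.csv",
        "basins": outdir / f"{name}-basins.csv",
        "tree": outdir / f"{name}-tree.nwk",
    }
    occ.to_csv(paths["occurrences"], index=False)
    bas.to_csv(paths["basins"], index=False)
    paths["tree"].write_text(tree + "\n")
    return paths
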