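"""Synthetic OTU-table generator with known ground truth.

Emulates a two-compartment (root endosphere ``G`` / rhizosphere soil ``T``)
by four-species by three-replicate amplicon survey and plants, per
compartment network:

* one star-shaped module per hub (the hub correlates with every spoke while
  spoke-spoke correlations stay below the edge threshold), giving the hub a
  within-module degree z-score of ~sqrt(module size - 1) > 2.5;
* dense near-clique modules whose members share a module factor at the
  configured within-module correlation;
* connector OTUs correlated with the members of three clique modules at
  once (participation coefficient ~2/3), with the same OTU ids in both
  compartments so cross-network shared connectors exist;
* a TOC gradient aligned with one clique factor that both attracts
  OTU-environment edges and modulates community evenness, planting a
  positive Shannon ~ TOC slope (TN carries no planted slope);
* a rhizosphere evenness boost (flatter rank-abundance curve) and a larger
  rhizosphere OTU pool, so diversity contrasts between compartments.

The correlation geometry is a fixed design: planted OTU profiles are
permutations of the per-compartment sample ranks with prescribed pairwise
Spearman correlations, and only the multinomial read sampling (and a small
lognormal jitter) consumes the user seed. Rank correlations between planted
OTUs are therefore reproducible by construction rather than drawn from a
stochastic factor model, which is what makes hub/connector geometry
attainable with only 12 samples per network.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .otu import RANKS, OtuTable, all_unclassified_lineage

logger = logging.getLogger("rhizonet")

# fixed design constant: the latent geometry is part of the generator's
# definition, independent of the user-facing seed
_DESIGN_SEED = 20240917

# genus -> (phylum, class, order, family, trophic_mode, guild, confidence)
# guild None => genus absent from the reference (unassigned)
_GENUS_TABLE = {
    "Tuber": ("Ascomycota", "Pezizomycetes", "Pezizales", "Tuberaceae",
              "symbiotroph", "Ectomycorrhizal", "highly probable"),
    "Russula": ("Basidiomycota", "Agaricomycetes", "Russulales", "Russulaceae",
                "symbiotroph", "Ectomycorrhizal", "highly probable"),
    "Sebacina": ("Basidiomycota", "Agaricomycetes", "Sebacinales", "Sebacinaceae",
                 "symbiotroph", "Ectomycorrhizal", "probable"),
    "Inocybe": ("Basidiomycota", "Agaricomycetes", "Agaricales", "Inocybaceae",
                "symbiotroph", "Ectomycorrhizal", "highly probable"),
    "Tomentella": ("Basidiomycota", "Agaricomycetes", "Thelephorales",
                   "Thelephoraceae", "symbiotroph", "Ectomycorrhizal", "probable"),
    "Chloridium": ("Ascomycota", "Sordariomycetes", "Chaetosphaeriales",
                   "Chaetosphaeriaceae", "saprotroph", "Undefined Saprotroph",
                   "probable"),
    "Acaulium": ("Ascomycota", "Sordariomycetes", "Microascales", "Microascaceae",
                 "saprotroph", "Undefined Saprotroph", "probable"),
    "Mortierella": ("Mortierellomycota", "Mortierellomycetes", "Mortierellales",
                    "Mortierellaceae", "saprotroph", "Soil Saprotroph", "probable"),
    "Penicillium": ("Ascomycota", "Eurotiomycetes", "Eurotiales", "Aspergillaceae",
                    "saprotroph", "Undefined Saprotroph", "highly probable"),
    "Exophiala": ("Ascomycota", "Eurotiomycetes", "Chaetothyriales",
                  "Herpotrichiellaceae", "saprotroph", "Undefined Saprotroph",
                  "possible"),
    "Fusarium": ("Ascomycota", "Sordariomycetes", "Hypocreales", "Nectriaceae",
                 "pathotroph", "Plant Pathogen", "probable"),
    "Alternaria": ("Ascomycota", "Dothideomycetes", "Pleosporales",
                   "Pleosporaceae", "pathotroph", "Plant Pathogen", "probable"),
    "Ilyonectria": ("Ascomycota", "Sordariomycetes", "Hypocreales", "Nectriaceae",
                    "pathotroph-saprotroph", "Plant Pathogen", "possible"),
    # multi-guild records: excluded from guild abundances by the
    # single-guild rule
    "Aspergillus": ("Ascomycota", "Eurotiomycetes", "Eurotiales",
                    "Aspergillaceae", "pathotroph-saprotroph",
                    "Plant Pathogen|Undefined Saprotroph", "possible"),
    "Clonostachys": ("Ascomycota", "Sordariomycetes", "Hypocreales",
                     "Bionectriaceae", "pathotroph-saprotroph",
                     "Fungal Parasite|Undefined Saprotroph", "possible"),
    # genera with no reference record at all (unassigned)
    "Saitozyma": ("Basidiomycota", "Tremellomycetes", "Tremellales",
                  "Trimorphomycetaceae", None, None, None),
    "Archaeorhizomyces": ("Ascomycota", "Archaeorhizomycetes",
                          "Archaeorhizomycetales", "Archaeorhizomycetaceae",
                          None, None, None),
}
# family-level reference record: OTUs resolved only to this family still match
_FAMILY_RECORDS = [
    ("Melanommataceae", "family", "saprotroph", "Undefined Saprotroph", "probable"),
]
_SYMBIOTROPH_GENERA = ["Tuber", "Russula", "Sebacina", "Inocybe", "Tomentella"]
_SAPROTROPH_GENERA = ["Chloridium", "Acaulium", "Mortierella", "Penicillium",
                      "Exophiala"]
_PATHOTROPH_GENERA = ["Fusarium", "Alternaria", "Ilyonectria"]
_MULTIGUILD_GENERA = ["Aspergillus", "Clonostachys"]
_UNASSIGNED_GENERA = ["Saitozyma", "Archaeorhizomyces"]

ENV_FACTORS = ("pH", "SWC", "TOC", "TN", "TP", "AP", "AK")


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the generated survey.

    Defaults reproduce the 2 compartments x 4 species x 3 replicates design
    (24 samples) with 200 endosphere and 500 rhizosphere OTUs at 30,000
    reads per sample, four planted modules per compartment network, a
    within-module correlation target of 0.8, one planted module hub and
    three shared connectors, a rhizosphere evenness boost of 1.5 and a
    planted Shannon-on-TOC slope of 0.05 nats per g/kg.
    """

    n_species_groups: int = 4
    n_replicates: int = 3
    compartments: tuple[str, str] = ("G", "T")
    n_otus_endosphere: int = 200
    n_otus_rhizosphere: int = 500
    depth_per_sample: int = 30000
    diversity_effect: float = 1.5
    n_planted_modules: int = 4
    module_within_corr: float = 0.8
    module_between_corr: float = 0.0
    n_planted_hubs: int = 1
    n_planted_connectors: int = 3
    clique_module_size: int = 16
    n_background_otus: int = 12
    toc_slope: float = 0.05
    noise_sd: float = 0.05
    seed: int = 0

    @property
    def n_samples_per_compartment(self) -> int:
        return self.n_species_groups * self.n_replicates

    @property
    def n_spokes(self) -> int:
        # star size 10 gives the hub a within-module degree z-score of
        # sqrt(9) = 3 when all spokes are recovered, with margin over the
        # 2.5 threshold even when a few spoke edges are lost
        return min(9, self.n_samples_per_compartment - 3)

    @property
    def star_module_size(self) -> int:
        return self.n_spokes + 1

    def validate(self) -> None:
        counts = (self.n_species_groups, self.n_replicates, self.n_otus_endosphere,
                  self.n_otus_rhizosphere, self.n_planted_modules,
                  self.clique_module_size)
        if any(c < 1 for c in counts):
            raise ValueError("all design counts must be >= 1")
        if self.depth_per_sample < 1:
            raise ValueError("depth_per_sample must be positive")
        if len(self.compartments) != 2:
            raise ValueError("exactly two compartments are supported")
        if not (0 < self.module_within_corr <= 1):
            raise ValueError("module_within_corr must be in (0, 1]")
        if self.module_within_corr <= self.module_between_corr:
            raise ValueError("module_within_corr must exceed module_between_corr")
        if self.n_planted_hubs >= self.n_planted_modules:
            raise ValueError("planted hubs exceed the available modules")
        n_cliques = self.n_planted_modules - self.n_planted_hubs
        if self.n_planted_connectors > 0 and n_cliques < 3:
            raise ValueError(
                "connectors need >= 3 clique modules "
                "(n_planted_modules - n_planted_hubs >= 3)"
            )
        if self.n_spokes < 3:
            raise ValueError("planted hubs exceed module size: too few samples "
                             "per compartment for a star module")
        if self.clique_module_size < 4:
            raise ValueError("clique_module_size must be >= 4")
        n_planted = (self.n_planted_hubs * self.star_module_size
                     + n_cliques * self.clique_module_size
                     + self.n_planted_connectors + self.n_background_otus)
        if min(self.n_otus_endosphere, self.n_otus_rhizosphere) < n_planted + 10:
            raise ValueError("OTU pools too small for the planted structure")


@dataclass
class GroundTruth:
    """What the generator planted, keyed by compartment label.

    ``planted_pairs`` lists the OTU pairs whose rank correlation was planted
    at/above the edge-detectable level (hub-spoke and within-clique pairs);
    spoke-spoke pairs of a star module are deliberately sub-threshold and
    are not planted pairs. Connectors are assigned the first clique module's
    id for coverage; module-recovery scores should exclude them.
    """

    module_assignment: dict[str, dict[str, int]]
    hub_otus: dict[str, list[str]]
    connector_otus: list[str]
    planted_pairs: dict[str, list[tuple[str, str, float]]]
    true_shannon: dict[str, float]
    env_effect: dict[str, float]

    def __post_init__(self) -> None:
        for comp, hubs in self.hub_otus.items():
            if set(hubs) & set(self.connector_otus):
                raise ValueError("hub and connector sets must be disjoint")


@dataclass
class SyntheticDataset:
    table: OtuTable
    env: pd.DataFrame
    guild_reference: "pd.DataFrame"
    truth: GroundTruth
    config: SyntheticConfig = field(repr=False, default=None)  # type: ignore


# ---------------------------------------------------------------------------
# latent geometry
# ---------------------------------------------------------------------------

# Per-compartment rank profiles are built directly in rank space: every
# planted OTU's cross-sample profile is a permutation of 1..n, so the
# Spearman correlation between two planted OTUs is fixed by construction
# (a Pearson-space factor design does not survive the rank transform at
# n = 12). Equal log-spacing between consecutive ranks keeps the realized
# ranks stable under multinomial read sampling; design targets sit slightly
# above the data-level targets to absorb the residual sampling attenuation.
_RANK_STEP = 0.42  # log-abundance gap between consecutive ranks

# rank-correlation design targets (pre-sign, absolute values)
_SPOKE_LOADING = 0.80  # hub-spoke: detectable but with sub-gate squares
_SPOKE_ACCEPT = (0.78, 0.84)  # accepted hub-spoke band after rank rounding
_SPOKE_CROSS_MAX = 0.63  # spoke-spoke design cap: below the gate after attenuation
_CENTER_WINDOW = (0.78, 0.82)  # clique centers around their common anchor
_CENTER_CROSS = (0.50, 0.58)  # pairwise clique-center correlation band
_GATEWAY_WINDOW = (0.96, 0.995)  # one near-center member per clique
_CONNECTOR_WINDOW = (0.93, 0.98)  # connectors around the center centroid
_CONNECTOR_CENTER_BAND = (0.78, 0.90)  # balanced pull toward each clique
_CROSS_MODULE_MAX = 0.58  # any cross-module planted pair stays below this


def _perm_rho(a: np.ndarray, b: np.ndarray, n: int) -> float:
    """Spearman correlation of two rank vectors (permutations of 1..n)."""
    c = (n + 1) / 2
    return float((a - c) @ (b - c) / (n * (n * n - 1) / 12))


def _rank_round(values: np.ndarray) -> np.ndarray:
    """Ranks (1..n) of a real vector: its nearest permutation profile."""
    return np.argsort(np.argsort(values)).astype(float) + 1.0


def _perturb_perm(center: np.ndarray, lo: float, hi: float,
                  rng: np.random.Generator, max_iter: int = 4000) -> np.ndarray:
    """Random transpositions of ``center`` until its rank correlation with
    the original falls inside [lo, hi]; swaps that overshoot are rejected."""
    n = len(center)
    p = center.astype(float).copy()
    for _ in range(max_iter):
        rho = _perm_rho(p, center, n)
        if rho <= hi:
            return p
        i, j = rng.choice(n, size=2, replace=False)
        q = p.copy()
        q[i], q[j] = q[j], q[i]
        if _perm_rho(q, center, n) >= lo:
            p = q
    return p


def _sample_perm(rng: np.random.Generator, n: int, center=None, window=None,
                 constraints=(), max_tries: int = 2000) -> np.ndarray:
    """A permutation near ``center`` (or uniform) satisfying |rho| bounds
    against previously placed profiles."""
    p = None
    for _ in range(max_tries):
        if center is None:
            p = rng.permutation(n) + 1.0
        else:
            p = _perturb_perm(center, window[0], window[1], rng)
        if all(abs(_perm_rho(p, v, n)) <= bound for v, bound in constraints):
            return p
    logger.warning("rank-design constraint relaxation after %d tries", max_tries)
    return p


def _spoke_violation(p: np.ndarray, hub: np.ndarray, spokes: list,
                     cross_rows: list) -> float:
    """How far a candidate spoke is from satisfying all design caps."""
    n = len(hub)
    v = 0.0
    rho = _perm_rho(p, hub, n)
    v += max(0.0, _SPOKE_ACCEPT[0] - rho) + max(0.0, rho - _SPOKE_ACCEPT[1])
    for q2 in spokes:
        v += max(0.0, abs(_perm_rho(p, q2, n)) - _SPOKE_CROSS_MAX)
    for r in cross_rows:
        v += max(0.0, abs(_perm_rho(p, r, n)) - _CROSS_MODULE_MAX)
    return v


def _repair_perm(p: np.ndarray, hub: np.ndarray, spokes: list, cross_rows: list,
                 rng: np.random.Generator, max_iter: int = 800) -> np.ndarray:
    """Hill-climb on transpositions to drive the violation score to zero."""
    n = len(p)
    best = p.copy()
    score = _spoke_violation(best, hub, spokes, cross_rows)
    for _ in range(max_iter):
        if score <= 0:
            break
        i, j = rng.choice(n, size=2, replace=False)
        q = best.copy()
        q[i], q[j] = q[j], q[i]
        s = _spoke_violation(q, hub, spokes, cross_rows)
        if s < score:
            best, score = q, s
    return best


def _star_spokes(hub: np.ndarray, n_spokes: int, rng: np.random.Generator,
                 cross_rows: list) -> list[np.ndarray]:
    """Spoke profiles around a hub whose pairwise correlations fall below
    the square of the hub loading.

    The spokes' deviations from the hub follow a simplex of directions in
    the orthogonal complement (pairwise cosine -1/(k-1)), which is the only
    way k profiles can all correlate with the hub at ~0.78 while their
    mutual correlations stay below the 0.6 edge gate.
    """
    n = len(hub)
    ch = hub - (n + 1) / 2
    ch = ch / np.linalg.norm(ch)
    c = _SPOKE_LOADING
    s = np.sqrt(1 - c * c)
    # simplex directions in the orthogonal complement of the hub profile
    m = rng.standard_normal((n, n_spokes))
    m -= m.mean(axis=0, keepdims=True)
    m -= np.outer(ch, ch @ m)
    q, _ = np.linalg.qr(m)
    u = q - q.mean(axis=1, keepdims=True)
    u /= np.linalg.norm(u, axis=0, keepdims=True)

    spokes: list[np.ndarray] = []
    for i in range(n_spokes):
        placed = None
        best, best_score = None, np.inf
        for _ in range(300):
            d = u[:, i] + 0.12 * rng.standard_normal(n)
            d -= d.mean()
            d -= (d @ ch) * ch
            d /= np.linalg.norm(d)
            p = _rank_round(c * ch + s * d)
            score = _spoke_violation(p, hub, spokes, cross_rows)
            if score <= 0:
                placed = p
                break
            if score < best_score:
                best, best_score = p, score
        if placed is None:
            # drive the best near-miss into the feasible region by local search
            placed = _repair_perm(best, hub, spokes, cross_rows, rng)
            if _spoke_violation(placed, hub, spokes, cross_rows) > 0.02:
                logger.debug("spoke %d placed with residual design violation", i)
        spokes.append(placed)
    return spokes


def _compartment_design(cfg: SyntheticConfig, rng: np.random.Generator) -> dict:
    """Rank profiles, module labels and planted pairs for one compartment."""
    n = cfg.n_samples_per_compartment
    n_hubs = cfg.n_planted_hubs
    n_spokes = cfg.n_spokes
    n_cliques = cfg.n_planted_modules - n_hubs
    # design loading slightly above sqrt(within_corr): pairwise member
    # correlations then land near within_corr in the sampled data
    loading = min(np.sqrt(cfg.module_within_corr) + 0.06, 0.97)
    member_window = (loading - 0.01, loading + 0.01)

    names: list[str] = []
    rank_rows: list[np.ndarray] = []
    signs: list[float] = []
    module_of: dict[str, int] = {}
    pairs_idx: list[tuple[int, int]] = []
    hub_names: list[str] = []
    connector_names: list[str] = []

    def add(name, ranks, sign, module):
        names.append(name)
        rank_rows.append(ranks)
        signs.append(sign)
        module_of[name] = module
        return len(names) - 1

    # clique centers share a common anchor so that a connector profile can
    # correlate with all of the first three cliques at once
    anchor = rng.permutation(n) + 1.0
    centers: list[np.ndarray] = []
    for k in range(n_cliques):
        if k < 3 and cfg.n_planted_connectors:
            for _ in range(2000):
                c = _perturb_perm(anchor, *_CENTER_WINDOW, rng=rng)
                if all(
                    _CENTER_CROSS[0] <= _perm_rho(c, prev, n) <= _CENTER_CROSS[1]
                    for prev in centers
                ):
                    break
        else:
            c = _sample_perm(rng, n, constraints=[(p, 0.5) for p in centers])
        centers.append(c)

    # connectors: rank-rounded centroid of the first three centers, jittered
    # and kept balanced (similar correlation to each of the three cliques)
    connector_rows: list[np.ndarray] = []
    connector_base = None
    if cfg.n_planted_connectors:
        centroid = np.sum([c - (n + 1) / 2 for c in centers[:3]], axis=0)
        connector_base = _rank_round(centroid)
        lo, hi = _CONNECTOR_CENTER_BAND
        for c in range(cfg.n_planted_connectors):
            v, best, best_spread = None, None, np.inf
            for _ in range(1500):
                cand = _perturb_perm(connector_base, *_CONNECTOR_WINDOW, rng=rng)
                rhos = [_perm_rho(cand, ck, n) for ck in centers[:3]]
                spread = max(rhos) - min(rhos)
                if min(rhos) >= lo and max(rhos) <= hi and spread <= 0.08:
                    v = cand
                    break
                if min(rhos) >= lo - 0.03 and spread < best_spread:
                    best, best_spread = cand, spread
            if v is None:
                v = best if best is not None else _perturb_perm(
                    connector_base, *_CONNECTOR_WINDOW, rng=rng
                )
                logger.warning("connector %d accepted with relaxed balance", c)
            connector_rows.append(v)

    # clique members around their center: one near-center "gateway" (the
    # anchor point for connector edges), two anti-correlated members, the
    # rest at the configured loading
    member_idx: list[list[int]] = []
    placed_members: list[tuple[np.ndarray, int]] = []  # (ranks, clique)
    for k in range(n_cliques):
        idxs = []
        # members are constrained against the other cliques' centers: that
        # caps the mean cross-module correlation, and the occasional pair
        # drifting above the gate stays within the spurious-edge budget
        constraints = [
            (c2, 0.66) for kk, c2 in enumerate(centers) if kk != k
        ]
        for j in range(cfg.clique_module_size):
            if j == 0 and k < 3 and connector_base is not None:
                # "gateway" member: sits between its clique center and the
                # connector direction, giving every connector one strong,
                # reliable anchor edge into this module
                ck = centers[k] - (n + 1) / 2
                vb = connector_base - (n + 1) / 2
                mix = 1.35 * ck / np.linalg.norm(ck) + 0.65 * vb / np.linalg.norm(vb)
                m = _rank_round(mix)
            elif j == 0:
                m = _sample_perm(
                    rng, n, center=centers[k], window=_GATEWAY_WINDOW,
                    constraints=constraints,
                )
            else:
                m = _sample_perm(
                    rng, n, center=centers[k], window=member_window,
                    constraints=constraints,
                )
            sign = -1.0 if j in (1, 2) and cfg.clique_module_size >= 8 else 1.0
            idxs.append(add(f"clq{k}_{j}", m, sign, n_hubs + k))
            placed_members.append((m, k))
        member_idx.append(idxs)
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                pairs_idx.append((idxs[a], idxs[b]))

    for c, v in enumerate(connector_rows):
        add(f"conn{c}", v, 1.0, n_hubs)  # nominal module; excluded from scores
        connector_names.append(f"conn{c}")

    # star modules: a hub far from the clique region plus simplex spokes
    cross_rows = [r for r, _ in placed_members] + connector_rows
    hub_anchor_rows = centers + connector_rows[:1]
    for h in range(n_hubs):
        hub = _sample_perm(
            rng, n,
            constraints=[(r, 0.45) for r in hub_anchor_rows]
            + [(rank_rows[i], 0.45) for i, nm in enumerate(names)
               if nm.startswith("hub")],
        )
        hub_i = add(f"hub{h}", hub, 1.0, h)
        hub_names.append(f"hub{h}")
        spokes = _star_spokes(hub, n_spokes, rng, cross_rows)
        for i, s in enumerate(spokes):
            sign = -1.0 if i < 2 else 1.0
            s_i = add(f"spoke{h}_{i}", s, sign, h)
            pairs_idx.append((hub_i, s_i))
        cross_rows.extend(spokes)

    # materialise: reversal implements negative association exactly in rank
    # space; values are equally spaced in log abundance
    latent = np.empty((len(names), n))
    for i, (ranks, sign) in enumerate(zip(rank_rows, signs)):
        r = ranks if sign > 0 else (n + 1) - ranks
        latent[i] = _RANK_STEP * (r - (n + 1) / 2)

    pairs = []
    for a, b in pairs_idx:
        rho = signs[a] * signs[b] * _perm_rho(rank_rows[a], rank_rows[b], n)
        pairs.append((names[a], names[b], float(rho)))

    toc_center = centers[-1] if centers else rank_rows[0]
    toc_pattern = (toc_center - (n + 1) / 2) / np.sqrt((n * n - 1) / 12.0)
    return {
        "names": names,
        "latent": latent,
        "module_of": module_of,
        "pairs": pairs,
        "hubs": hub_names,
        "connectors": connector_names,
        "toc_pattern": toc_pattern,
    }


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _species_labels(k: int) -> list[str]:
    base = ["PZ", "CZ", "OZ", "ZJ"]
    return base[:k] + [f"SP{i}" for i in range(5, k + 1)][: max(0, k - 4)]


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate the OTU table, environment table, guild reference and truth.

    Deterministic given ``config.seed``: the latent geometry is fixed by
    design, and the user seed drives only the lognormal jitter, the
    multinomial read sampling and small environmental noise.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    n_per = cfg.n_samples_per_compartment
    species = _species_labels(cfg.n_species_groups)
    design_rng = np.random.default_rng(_DESIGN_SEED)
    user_rng = np.random.default_rng(cfg.seed)

    comp_designs = {comp: _compartment_design(cfg, design_rng)
                    for comp in cfg.compartments}

    # sample bookkeeping (endosphere first, species-major order)
    sample_ids, meta_rows = [], []
    for comp in cfg.compartments:
        for sp in species:
            for rep in range(1, cfg.n_replicates + 1):
                sample_ids.append(f"{comp}_{sp}_{rep}")
                meta_rows.append((comp, sp, rep))
    metadata = pd.DataFrame(
        meta_rows, columns=["compartment", "species", "replicate"], index=sample_ids
    )
    metadata.index.name = "sample_id"

    # global OTU id assignment: connectors and background OTUs are shared
    # between compartments, module members and the rare tail are not
    endo, rhizo = cfg.compartments
    n_planted = {c: len(comp_designs[c]["names"]) for c in cfg.compartments}
    n_conn = cfg.n_planted_connectors
    pool_size = {endo: cfg.n_otus_endosphere, rhizo: cfg.n_otus_rhizosphere}
    n_rare = {
        c: pool_size[c] - (n_planted[c] - n_conn) - n_conn - cfg.n_background_otus
        for c in cfg.compartments
    }
    counter = [0]

    def next_ids(k: int) -> list[str]:
        ids = [f"OTU{counter[0] + i + 1}" for i in range(k)]
        counter[0] += k
        return ids

    conn_ids = next_ids(n_conn)
    local_to_global: dict[str, dict[str, str]] = {}
    for comp in cfg.compartments:
        design = comp_designs[comp]
        mapping = {}
        conn_iter = iter(conn_ids)
        module_names = [nm for nm in design["names"] if nm not in design["connectors"]]
        fresh = iter(next_ids(len(module_names)))
        for nm in design["names"]:
            mapping[nm] = next(conn_iter) if nm in design["connectors"] else next(fresh)
        local_to_global[comp] = mapping
    background_ids = next_ids(cfg.n_background_otus)
    rare_ids = {c: next_ids(n_rare[c]) for c in cfg.compartments}
    all_otus = (
        conn_ids
        + [local_to_global[c][nm] for c in cfg.compartments
           for nm in comp_designs[c]["names"] if nm not in comp_designs[c]["connectors"]]
        + background_ids
        + rare_ids[endo]
        + rare_ids[rhizo]
    )

    # base abundances (design-fixed)
    def lognormal_props(rng, k, sigma):
        x = np.exp(rng.normal(0.0, sigma, size=k))
        return x / x.sum()

    def planted_bases(comp):
        # rank fidelity under multinomial sampling grows with abundance, so
        # the structurally critical OTUs (hub, spokes, connectors, gateways)
        # take the top base abundances
        names = comp_designs[comp]["names"]
        props = np.sort(lognormal_props(design_rng, len(names), 0.25))[::-1]

        def tier(nm):
            if nm.startswith(("hub", "spoke")):
                return 0
            if nm.startswith("conn") or nm.endswith("_0"):
                return 1
            return 2

        order = sorted(range(len(names)), key=lambda i: (tier(names[i]), i))
        out = np.empty(len(names))
        out[order] = props
        return out

    base_planted = {c: planted_bases(c) for c in cfg.compartments}
    base_background = lognormal_props(design_rng, cfg.n_background_otus, 0.45)
    rare_prop = {
        c: design_rng.uniform(0.8e-5, 3.0e-5, size=n_rare[c])
        for c in cfg.compartments
    }
    species_effect = design_rng.normal(
        0.0, 0.5, size=(cfg.n_background_otus, cfg.n_species_groups)
    )

    # environment design: TOC follows the last clique factor of each
    # compartment; TN is pure noise (no planted slope)
    toc_sd, toc_mean = 2.0, {endo: 13.0, rhizo: 16.0}
    env_rows: dict[str, dict[str, float]] = {}
    toc_z: dict[str, float] = {}
    env_noise_pattern = {
        f: design_rng.standard_normal(2 * n_per) for f in ("TN", "TP", "AP", "AK", "SWC")
    }
    for ci, comp in enumerate(cfg.compartments):
        direction = comp_designs[comp]["toc_pattern"]
        for si in range(n_per):
            sid = sample_ids[ci * n_per + si]
            z = float(direction[si])
            toc_z[sid] = z
            gi = ci * n_per + si
            env_rows[sid] = {
                "pH": 5.9 + 0.5 * ci + 0.1 * float(user_rng.normal()),
                "SWC": 21.0 + 3.0 * ci + 1.2 * env_noise_pattern["SWC"][gi]
                + 0.2 * float(user_rng.normal()),
                "TOC": 0.0,  # filled once the design-level Shannon is known
                "TN": 1.6 + 0.25 * env_noise_pattern["TN"][gi]
                + 0.02 * float(user_rng.normal()),
                "TP": 0.9 + 0.1 * env_noise_pattern["TP"][gi]
                + 0.01 * float(user_rng.normal()),
                "AP": 12.0 + 2.0 * env_noise_pattern["AP"][gi]
                + 0.2 * float(user_rng.normal()),
                "AK": 110.0 + 15.0 * env_noise_pattern["AK"][gi]
                + 1.0 * float(user_rng.normal()),
            }
    env = pd.DataFrame.from_dict(env_rows, orient="index").loc[sample_ids, list(ENV_FACTORS)]
    env.index.name = "sample_id"

    # per-sample proportions and multinomial counts
    counts = np.zeros((len(sample_ids), len(all_otus)), dtype=np.int64)
    col_index = {otu: j for j, otu in enumerate(all_otus)}
    true_shannon: dict[str, float] = {}

    n_balancers = min(4, cfg.n_background_otus - 2)
    n_mids = cfg.n_background_otus - n_balancers
    background_noise = {
        comp: design_rng.standard_normal((n_mids, n_per))
        for comp in cfg.compartments
    }
    balancer_noise = {
        comp: design_rng.standard_normal((n_balancers, n_per))
        for comp in cfg.compartments
    }
    for ci, comp in enumerate(cfg.compartments):
        design = comp_designs[comp]
        mapping = local_to_global[comp]
        # rhizosphere samples get a flatter rank-abundance curve: the whole
        # log-abundance profile is shrunk by 1/diversity_effect, which is
        # rank-preserving per OTU and so leaves the planted correlations alone
        flatten = 1.0 / cfg.diversity_effect if comp == rhizo else 1.0

        lb_planted = np.log(base_planted[comp])
        lb_background = np.log(base_background[:n_mids] * 0.35)
        lb = np.concatenate([lb_planted, lb_background])
        weights = np.exp(lb) / np.exp(lb).sum()
        centered = lb - np.average(lb, weights=weights)
        tail_share = float(rare_prop[comp].sum())
        latent = design["latent"]  # rank-profile log deviations
        n_main = len(lb)
        n_planted_rows = len(lb_planted)
        sp_idx_of = [
            species.index(metadata.loc[sample_ids[ci * n_per + si], "species"])
            for si in range(n_per)
        ]
        toc_zc = np.array([toc_z[sample_ids[ci * n_per + si]] for si in range(n_per)])

        def assemble(noise):
            """Unnormalised planted+mid abundances and the balancer masses.

            The "balancer" background OTUs absorb the per-sample mass
            fluctuation, so the compositional closure constant is the same
            in every sample and planted rank profiles survive normalisation
            intact.
            """
            vals = np.empty((n_main, n_per))
            for si in range(n_per):
                x = np.empty(n_main)
                x[:n_planted_rows] = centered[:n_planted_rows] + latent[:, si]
                x[n_planted_rows:] = (
                    centered[n_planted_rows:]
                    + species_effect[:n_mids, sp_idx_of[si]]
                    + 0.7 * background_noise[comp][:, si]
                )
                x += noise[:, si]
                vals[:, si] = np.exp(flatten * x)
            sums = vals.sum(axis=0)
            total = 1.35 * sums.max()
            bal_w = np.exp(0.35 * balancer_noise[comp])
            bal_w /= bal_w.sum(axis=0, keepdims=True)
            bal_vals = bal_w * (total - sums)
            return vals, bal_vals, total

        def design_shannon():
            vals, bal_vals, total = assemble(np.zeros((n_main, n_per)))
            main = np.vstack([vals, bal_vals]) / total * (1.0 - tail_share)
            h = np.empty(n_per)
            for si in range(n_per):
                p = np.concatenate([main[:, si], rare_prop[comp]])
                p = p[p > 0]
                p = p / p.sum()
                h[si] = -(p * np.log(p)).sum()
            return h

        # Community evenness co-varies with the TOC-aligned module factor by
        # construction; the TOC axis is scaled so that the design-level
        # Shannon ~ TOC relation realises toc_slope (nats per g/kg). With
        # toc_slope = 0 the TOC values are instead pure seed-driven noise,
        # uncoupled from the community.
        comp_sids = [sample_ids[ci * n_per + si] for si in range(n_per)]
        if cfg.toc_slope > 0 and np.ptp(toc_zc) > 0:
            slope_z = stats.linregress(toc_zc, design_shannon()).slope
            scale = slope_z / cfg.toc_slope
            scale = float(np.clip(scale, -8.0, 8.0))
            for si, sid in enumerate(comp_sids):
                env.loc[sid, "TOC"] = (
                    toc_mean[comp] + scale * toc_zc[si]
                    + 0.1 * float(user_rng.normal())
                )
        else:
            for sid in comp_sids:
                env.loc[sid, "TOC"] = toc_mean[comp] + toc_sd * float(user_rng.normal())

        noise = user_rng.normal(0.0, cfg.noise_sd, size=(n_main, n_per))
        vals, bal_vals, total = assemble(noise)
        for si in range(n_per):
            gi = ci * n_per + si
            sid = sample_ids[gi]
            scale = (1.0 - tail_share) / total
            full = np.zeros(len(all_otus))
            for idx, nm in enumerate(design["names"]):
                full[col_index[mapping[nm]]] = vals[idx, si] * scale
            for idx in range(n_mids):
                full[col_index[background_ids[idx]]] = (
                    vals[n_planted_rows + idx, si] * scale
                )
            for idx in range(n_balancers):
                full[col_index[background_ids[n_mids + idx]]] = (
                    bal_vals[idx, si] * scale
                )
            for idx, otu in enumerate(rare_ids[comp]):
                full[col_index[otu]] = rare_prop[comp][idx]
            full /= full.sum()
            p_nz = full[full > 0]
            true_shannon[sid] = float(-(p_nz * np.log(p_nz)).sum())
            counts[gi] = user_rng.multinomial(cfg.depth_per_sample, full)

    counts_df = pd.DataFrame(counts, index=sample_ids, columns=all_otus)

    # taxonomy and guild reference
    taxonomy = _assign_taxonomy(
        cfg, comp_designs, local_to_global, background_ids, rare_ids, design_rng
    )
    guild_reference = _build_guild_reference()

    # ground truth
    module_assignment, hub_otus, planted_pairs = {}, {}, {}
    for comp in cfg.compartments:
        design = comp_designs[comp]
        mapping = local_to_global[comp]
        module_assignment[comp] = {
            mapping[nm]: int(m) for nm, m in design["module_of"].items()
        }
        hub_otus[comp] = [mapping[nm] for nm in design["hubs"]]
        planted_pairs[comp] = [
            (mapping[a], mapping[b], float(r)) for a, b, r in design["pairs"]
        ]
    env_effect = {"TN": 0.0}
    slopes = []
    for comp in cfg.compartments:
        sids = [s for s in sample_ids if metadata.loc[s, "compartment"] == comp]
        h = np.array([true_shannon[s] for s in sids])
        t = env.loc[sids, "TOC"].to_numpy()
        if np.ptp(t) > 0:
            slopes.append(float(stats.linregress(t, h).slope))
    env_effect["TOC"] = float(np.mean(slopes)) if slopes else 0.0
    truth = GroundTruth(
        module_assignment=module_assignment,
        hub_otus=hub_otus,
        connector_otus=list(conn_ids),
        planted_pairs=planted_pairs,
        true_shannon=true_shannon,
        env_effect=env_effect,
    )
    table = OtuTable(counts_df, metadata, taxonomy)
    return SyntheticDataset(table, env, guild_reference, truth, cfg)


def _assign_taxonomy(cfg, comp_designs, local_to_global, background_ids,
                     rare_ids, rng) -> pd.DataFrame:
    """Genus-level lineages from a fixed pool; the endosphere planted OTUs
    lean symbiotrophic, the rhizosphere ones saprotrophic/pathotrophic."""
    endo, rhizo = cfg.compartments
    rows: dict[str, dict[str, str]] = {}

    def lineage_for(genus: str | None, family_only: str | None = None):
        if family_only is not None:
            # resolved to family only (e.g. unclassified_f__Melanommataceae)
            out = {
                "kingdom": "Fungi", "phylum": "Ascomycota",
                "class": "Dothideomycetes", "order": "Pleosporales",
                "family": family_only,
                "genus": f"unclassified_f__{family_only}",
                "species": f"unclassified_f__{family_only}",
            }
            return out
        if genus is None:
            return all_unclassified_lineage()
        phylum, cls, order, family = _GENUS_TABLE[genus][:4]
        return {
            "kingdom": "Fungi", "phylum": phylum, "class": cls, "order": order,
            "family": family, "genus": genus,
            "species": f"unclassified_g__{genus}",
        }

    for comp in cfg.compartments:
        design = comp_designs[comp]
        mapping = local_to_global[comp]
        if comp == endo:
            main_pool = _SYMBIOTROPH_GENERA
            minor_pool = _SAPROTROPH_GENERA + _PATHOTROPH_GENERA
        else:
            main_pool = _SAPROTROPH_GENERA
            minor_pool = _PATHOTROPH_GENERA + _SYMBIOTROPH_GENERA[:1]
        for i, nm in enumerate(design["names"]):
            otu = mapping[nm]
            if otu in rows:
                continue
            if nm in design["hubs"] and comp == endo:
                rows[otu] = lineage_for(None, family_only="Melanommataceae")
            elif i % 7 == 6:
                rows[otu] = lineage_for(_MULTIGUILD_GENERA[i % len(_MULTIGUILD_GENERA)])
            else:
                pool = main_pool if i % 4 else minor_pool
                rows[otu] = lineage_for(pool[i % len(pool)])
    for i, otu in enumerate(background_ids):
        pool = (_SAPROTROPH_GENERA + _PATHOTROPH_GENERA + _MULTIGUILD_GENERA
                + _UNASSIGNED_GENERA)
        rows[otu] = lineage_for(pool[i % len(pool)])
    for comp in cfg.compartments:
        for i, otu in enumerate(rare_ids[comp]):
            if i % 3 == 0:
                rows[otu] = lineage_for(_UNASSIGNED_GENERA[i % len(_UNASSIGNED_GENERA)])
            else:
                rows[otu] = all_unclassified_lineage()
    tax = pd.DataFrame.from_dict(rows, orient="index")
    return tax[list(RANKS)]


def _build_guild_reference() -> pd.DataFrame:
    rows = []
    for genus, rec in _GENUS_TABLE.items():
        phylum, cls, order, family, mode, guild, conf = rec
        if mode is None:
            continue
        rows.append((genus, "genus", mode, guild, conf))
    rows.extend(_FAMILY_RECORDS)
    return pd.DataFrame(
        rows, columns=["taxon", "level", "trophic_mode", "guild", "confidence"]
    )


# ---------------------------------------------------------------------------
# fixture I/O and evaluation helpers
# ---------------------------------------------------------------------------

def write_fixture(dataset: SyntheticDataset, directory) -> dict[str, str]:
    """Write otu_table/taxonomy/metadata/env/guilds TSVs plus truth.json."""
    from .otu import write_otu_table

    os.makedirs(directory, exist_ok=True)
    paths = write_otu_table(dataset.table, directory)
    env_path = os.path.join(directory, "env.tsv")
    dataset.env.to_csv(env_path, sep="\t")
    paths["env"] = env_path
    guild_path = os.path.join(directory, "guilds.tsv")
    dataset.guild_reference.to_csv(guild_path, sep="\t", index=False)
    paths["guilds"] = guild_path
    truth_path = os.path.join(directory, "truth.json")
    with open(truth_path, "wt", encoding="utf-8") as fh:
        json.dump(asdict(dataset.truth), fh, indent=1, sort_keys=True)
    paths["truth"] = truth_path
    return paths


def read_truth(path) -> GroundTruth:
    with open(path, "rt", encoding="utf-8") as fh:
        raw = json.load(fh)
    raw["planted_pairs"] = {
        comp: [tuple(p) for p in pairs] for comp, pairs in raw["planted_pairs"].items()
    }
    return GroundTruth(**raw)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions of the same items."""
    a = pd.Categorical(list(labels_a)).codes
    b = pd.Categorical(list(labels_b)).codes
    if len(a) != len(b):
        raise ValueError("label sequences differ in length")
    contingency = pd.crosstab(a, b).to_numpy()

    def comb2(x):
        x = np.asarray(x, dtype=float)
        return (x * (x - 1) / 2).sum()

    sum_ij = comb2(contingency)
    sum_a = comb2(contingency.sum(axis=1))
    sum_b = comb2(contingency.sum(axis=0))
    n_pairs = comb2([len(a)])
    expected = sum_a * sum_b / n_pairs if n_pairs else 0.0
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def edge_recovery(graph, planted_pairs) -> float:
    """Fraction of planted pairs present as edges in a built network."""
    if not planted_pairs:
        return float("nan")
    hits = sum(1 for a, b, _ in planted_pairs if graph.has_edge(a, b))
    return hits / len(planted_pairs)


def module_recovery_ari(partition_assignment: dict, truth: GroundTruth,
                        compartment: str) -> float:
    """ARI between the detected partition and the planted modules, over
    planted module members recovered in the network (connectors excluded)."""
    planted = truth.module_assignment[compartment]
    exclude = set(truth.connector_otus)
    common = [o for o in planted if o in partition_assignment and o not in exclude]
    if not common:
        return float("nan")
    return adjusted_rand_index(
        [planted[o] for o in common], [partition_assignment[o] for o in common]
    )
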