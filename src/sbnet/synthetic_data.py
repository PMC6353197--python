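"""Synthetic survey data from a known ground-truth Bayesian network.

Generates Eurobarometer-like categorical data so that every downstream stage
(recoding, structure learning, bootstrap averaging, network statistics) can be
exercised and tested without access to the real microdata.  The generating
process is a discrete Bayesian network with Dirichlet-sampled conditional
probability tables; macro-scope variables are drawn once per simulated region
and copied to all of its members.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .dataset import CategoricalDataset
from .schema import SB_VARIABLE, VariableSchema, schema_by_name, default_survey_schema

__all__ = [
    "GroundTruthModel",
    "build_ground_truth",
    "default_test_model",
    "sample_categorical",
    "sample_dataset",
    "decode_to_raw",
    "inject_missing",
]


# --------------------------------------------------------------------------- #
# ground-truth model
# --------------------------------------------------------------------------- #

@dataclasses.dataclass
class GroundTruthModel:
    """A discrete Bayesian network used as the simulation ground truth.

    ``cpts[name]`` has shape ``(q, k)`` where ``q`` is the number of parent
    configurations (product of parent cardinalities, row-major in the order of
    ``parents[name]``) and ``k`` the variable's own cardinality.
    """

    schema: list[VariableSchema]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]
    n_regions: int = 20

    def __post_init__(self) -> None:
        self._by_name = schema_by_name(self.schema)
        g = self.dag()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ground-truth graph contains a cycle: {cycle}")
        for var in self.schema:
            pars = self.parents.get(var.name, ())
            q = int(np.prod([self._by_name[p].cardinality for p in pars], dtype=np.int64))
            cpt = np.asarray(self.cpts[var.name], dtype=float)
            if cpt.shape != (q, var.cardinality):
                raise ValueError(
                    f"CPT for {var.name!r} has shape {cpt.shape}, expected "
                    f"({q}, {var.cardinality})"
                )
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-12, rtol=0.0):
                raise ValueError(f"CPT rows for {var.name!r} do not sum to 1")
            if var.scope == "macro":
                bad = [p for p in pars if self._by_name[p].scope != "macro"]
                if bad:
                    raise ValueError(
                        f"macro variable {var.name!r} has micro parents {bad}"
                    )

    def dag(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(v.name for v in self.schema)
        for child, pars in self.parents.items():
            for p in pars:
                g.add_edge(p, child)
        return g

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(
            (p, c) for c, pars in self.parents.items() for p in pars
        )

    def skeleton_edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges}

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_regions": self.n_regions,
            "variables": [
                {
                    "name": v.name,
                    "cluster": v.cluster,
                    "levels": list(v.levels),
                    "scope": v.scope,
                    "parents": list(self.parents.get(v.name, ())),
                    "cpt": np.asarray(self.cpts[v.name]).tolist(),
                }
                for v in self.schema
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "GroundTruthModel":
        schema = [
            VariableSchema(d["name"], d["cluster"], tuple(d["levels"]), d["scope"])
            for d in doc["variables"]
        ]
        parents = {d["name"]: tuple(d["parents"]) for d in doc["variables"]}
        cpts = {d["name"]: np.asarray(d["cpt"], dtype=float) for d in doc["variables"]}
        return cls(schema, parents, cpts, n_regions=int(doc.get("n_regions", 20)))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "GroundTruthModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sample_cpts(
    schema: Sequence[VariableSchema],
    parents: dict[str, tuple[str, ...]],
    effect_strength: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Dirichlet CPTs with concentration 1/effect_strength.

    Larger ``effect_strength`` gives sharper rows, hence stronger (more
    detectable) parent-child dependence.
    """
    by_name = schema_by_name(schema)
    alpha = 1.0 / float(effect_strength)
    cpts = {}
    for var in schema:
        pars = parents.get(var.name, ())
        q = int(np.prod([by_name[p].cardinality for p in pars], dtype=np.int64))
        cpts[var.name] = rng.dirichlet(np.full(var.cardinality, alpha), size=q)
    return cpts


def build_ground_truth(
    seed: int,
    schema: Sequence[VariableSchema] | None = None,
    edge_density: float = 0.1,
    effect_strength: float = 2.0,
    edges: Iterable[tuple[str, str]] | None = None,
    n_regions: int = 20,
) -> GroundTruthModel:
    """Construct a random (or user-specified) acyclic ground-truth model.

    Random structure: nodes are ordered with macro variables first (so macro
    variables never acquire micro parents), ``round(edge_density * n_pairs)``
    node pairs are selected uniformly and each is oriented along that order.
    The SB variable is guaranteed at least one neighbour.
    """
    if not (0.0 < edge_density <= 1.0):
        raise ValueError("edge_density must be in (0, 1]")
    if effect_strength <= 0:
        raise ValueError("effect_strength must be > 0")
    schema = list(schema) if schema is not None else default_survey_schema()
    by_name = schema_by_name(schema)
    rng = np.random.default_rng(np.random.SeedSequence([834923, int(seed)]))

    names = [v.name for v in schema]
    if edges is not None:
        edge_list = [tuple(e) for e in edges]
        g = nx.DiGraph()
        g.add_nodes_from(names)
        g.add_edges_from(edge_list)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"user-supplied edge list contains a cycle: {cycle}")
    else:
        # topological order: demographics, then macro, then micro (shuffled
        # within scope).  Demographic variables stay parentless roots and
        # macro variables never acquire micro parents.
        demo = [n for n in names if by_name[n].cluster == "demographic"]
        macro = [n for n in names if by_name[n].scope == "macro" and n not in demo]
        micro = [n for n in names if by_name[n].scope == "micro" and n not in demo]
        rng.shuffle(macro)
        rng.shuffle(micro)
        order = demo + macro + micro
        pos = {n: i for i, n in enumerate(order)}

        def allowed_pair(a: str, b: str) -> bool:
            a_demo, b_demo = a in demo, b in demo
            if a_demo and b_demo:
                return False  # keep demographics mutually independent roots
            if (a_demo and by_name[b].scope == "macro") or (
                b_demo and by_name[a].scope == "macro"
            ):
                return False  # a demographic parent would be a micro parent
            return True

        pairs = [
            (a, b)
            for i, a in enumerate(names)
            for b in names[i + 1 :]
            if allowed_pair(a, b)
        ]
        n_edges = int(round(edge_density * len(names) * (len(names) - 1) / 2))
        n_edges = max(1, min(n_edges, len(pairs)))
        chosen = rng.choice(len(pairs), size=n_edges, replace=False)
        edge_list = []
        for idx in sorted(chosen):
            a, b = pairs[idx]
            edge_list.append((a, b) if pos[a] < pos[b] else (b, a))
        if SB_VARIABLE in by_name and not any(SB_VARIABLE in e for e in edge_list):
            other = next(n for n in order if n != SB_VARIABLE)
            pair = (other, SB_VARIABLE) if pos[other] < pos[SB_VARIABLE] else (
                SB_VARIABLE, other
            )
            edge_list[-1] = pair

    parents: dict[str, tuple[str, ...]] = {n: () for n in names}
    for p, c in sorted(edge_list):
        parents[c] = tuple(sorted(set(parents[c]) | {p}))
    cpts = _sample_cpts(schema, parents, effect_strength, rng)
    # balanced marginals for parentless demographics so strata have usable n
    balanced = {"sex": [0.5, 0.5], "age_group": [0.12, 0.31, 0.33, 0.24]}
    for name, probs in balanced.items():
        if name in parents and not parents[name] and len(probs) == by_name[name].cardinality:
            cpts[name] = np.asarray([probs], dtype=float)
    return GroundTruthModel(schema, parents, cpts, n_regions=n_regions)


def default_test_model(seed: int = 0, effect_strength: float = 3.0) -> GroundTruthModel:
    """Hand-specified 10-node, 12-edge ground truth used by recovery tests.

    Mirrors the survey network qualitatively (occupation-sitting,
    region-GDP and urbanity-facility links) with small cardinalities so that
    stochastic recovery tests are stable and fast.
    """
    t3 = ("t1", "t2", "t3")
    schema = [
        VariableSchema("region", "built_natural", ("west", "south", "east"), "macro"),
        VariableSchema("gdp", "politics_economics", t3, "macro"),
        VariableSchema("urbanity", "built_natural", ("rural", "town", "city")),
        VariableSchema("facility", "built_natural", ("low", "high")),
        VariableSchema("occupation", "institutional_home",
                       ("manual", "desk", "retired", "student")),
        VariableSchema("education", "institutional_home", ("le15", "16_19", "ge20")),
        VariableSchema("social_class", "institutional_home", ("working", "middle")),
        VariableSchema("sitting", "psychology_behaviour",
                       ("le2h30", "2h31_4h30", "4h31_7h30", "ge7h31")),
        VariableSchema("sex", "demographic", ("female", "male")),
        VariableSchema("age_group", "demographic", ("15_25", "26_44", "45_64", "65plus")),
    ]
    edges = [
        ("region", "gdp"),
        ("gdp", "urbanity"),
        ("gdp", "facility"),
        ("urbanity", "facility"),
        ("urbanity", "sitting"),
        ("sex", "occupation"),
        ("sex", "sitting"),
        ("age_group", "education"),
        ("age_group", "occupation"),
        ("education", "occupation"),
        ("education", "social_class"),
        ("occupation", "sitting"),
    ]
    return build_ground_truth(
        seed=seed,
        schema=schema,
        edges=edges,
        effect_strength=effect_strength,
        n_regions=12,
    )


# --------------------------------------------------------------------------- #
# sampling
# --------------------------------------------------------------------------- #

def _draw_categorical(cpt_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised draw: row i ~ Categorical(cpt_rows[i])."""
    u = rng.random(cpt_rows.shape[0])
    cum = np.cumsum(cpt_rows, axis=1)
    return (u[:, None] > cum).sum(axis=1).astype(np.int32)


def sample_categorical(
    model: GroundTruthModel,
    n: int,
    seed: int,
    return_regions: bool = False,
):
    """Ancestral sampling in topological order; returns a CategoricalDataset.

    Macro-scope variables are drawn once per region and broadcast to rows.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([219041, int(seed)]))
    by_name = schema_by_name(model.schema)
    order = list(nx.topological_sort(model.dag()))
    region_ids = rng.integers(0, model.n_regions, size=n).astype(np.int32)

    region_vals: dict[str, np.ndarray] = {}  # per-region draws, len n_regions
    row_vals: dict[str, np.ndarray] = {}  # per-row values, len n

    for name in order:
        var = by_name[name]
        pars = model.parents.get(name, ())
        cpt = model.cpts[name]
        if var.scope == "macro":
            cfg = np.zeros(model.n_regions, dtype=np.int64)
            for p in pars:
                cfg = cfg * by_name[p].cardinality + region_vals[p]
            vals = _draw_categorical(cpt[cfg], rng)
            region_vals[name] = vals
            row_vals[name] = vals[region_ids] if n else np.empty(0, dtype=np.int32)
        else:
            cfg = np.zeros(n, dtype=np.int64)
            for p in pars:
                cfg = cfg * by_name[p].cardinality + row_vals[p]
            row_vals[name] = _draw_categorical(cpt[cfg], rng) if n else np.empty(
                0, dtype=np.int32
            )

    mat = (
        np.column_stack([row_vals[v.name] for v in model.schema])
        if n
        else np.empty((0, len(model.schema)), dtype=np.int32)
    )
    ds = CategoricalDataset(model.schema, mat)
    if return_regions:
        return ds, region_ids
    return ds


# --------------------------------------------------------------------------- #
# decoding categorical draws back to raw survey fields
# --------------------------------------------------------------------------- #

# countries of the 2013 EU-28, grouped by geographic region
COUNTRIES_BY_REGION = {
    "western_central": ["AT", "BE", "DE", "FR", "IE", "LU", "NL", "GB"],
    "southern": ["CY", "ES", "GR", "HR", "IT", "MT", "PT", "SI"],
    "northern": ["DK", "EE", "FI", "LT", "LV", "SE"],
    "eastern": ["BG", "CZ", "HU", "PL", "RO", "SK"],
}
ALL_COUNTRIES = sorted(c for cs in COUNTRIES_BY_REGION.values() for c in cs)

# 18 raw occupation codes -> 8 condensed categories (1-based raw codes)
OCC18_TO_8 = {
    1: 5, 2: 8, 3: 6, 4: 7,
    5: 1, 6: 1, 7: 1, 8: 1, 9: 1,
    10: 2, 11: 2, 12: 2,
    13: 3, 14: 3,
    15: 4, 16: 4, 17: 4, 18: 4,
}

# 14 relationship codes -> (partner, children) flags (1-based raw codes)
REL14_TO_FLAGS = {
    1: (1, 0), 2: (1, 1), 3: (1, 0), 4: (1, 1), 5: (1, 0), 6: (1, 1), 7: (1, 1),
    8: (0, 0), 9: (0, 1), 10: (0, 0), 11: (0, 1), 12: (0, 0), 13: (0, 1), 14: (0, 0),
}

# 10 IPAQ sitting categories -> 4 bands (1-based raw codes)
SITTING10_TO_4 = {1: 1, 2: 1, 3: 1, 4: 2, 5: 2, 6: 3, 7: 3, 8: 3, 9: 4, 10: 4}

_AGE_RANGES = {"15_25": (15, 25), "26_44": (26, 44), "45_64": (45, 64), "65plus": (65, 89)}

_MACRO_NUMERIC_RANGES = {
    "social_media": {"below_avg": (25.0, 45.0), "above_avg": (55.0, 75.0)},
    "healthcare_provision": {"t1": (200.0, 349.0), "t2": (350.0, 499.0), "t3": (500.0, 700.0)},
    "chronic_disease": {"below_avg": (15.0, 25.0), "above_avg": (30.0, 40.0)},
    "temperature": {"cold": (-5.0, 9.4), "moderate": (10.0, 15.0), "hot": (15.6, 25.0)},
    "precipitation": {"dry": (0.0, 0.19), "moderate": (0.2, 2.0), "wet": (2.05, 5.0)},
    "gdp": {"t1": (10.0, 20.0), "t2": (21.0, 30.0), "t3": (31.0, 45.0)},
}
_MACRO_RAW_NAMES = {
    "social_media": "social_media_pct",
    "healthcare_provision": "healthcare_personnel",
    "chronic_disease": "chronic_disease_pct",
    "temperature": "temp_max_avg",
    "precipitation": "precip_daily_avg",
    "gdp": "gdp_eur",
}


def _pick(options_per_level: dict[int, list], codes: np.ndarray,
          rng: np.random.Generator) -> np.ndarray:
    """For each row, pick uniformly among the raw options of its level."""
    out = np.empty(codes.shape[0], dtype=object)
    for level, opts in options_per_level.items():
        mask = codes == level
        k = int(mask.sum())
        if k:
            out[mask] = rng.choice(np.asarray(opts, dtype=object), size=k)
    return out


def decode_to_raw(
    data: CategoricalDataset, region_ids: np.ndarray, seed: int
) -> pd.DataFrame:
    """Expand a categorical sample into raw Eurobarometer-like survey fields.

    Variables with a known decoder become their raw instrument fields (e.g.
    the 4-band sitting variable becomes a 10-category IPAQ response);
    variables without a decoder pass through as integer-coded columns.
    Macro numeric fields are drawn once per region.
    """
    rng = np.random.default_rng(np.random.SeedSequence([550137, int(seed)]))
    n = data.n_rows
    region_ids = np.asarray(region_ids, dtype=np.int64)
    raw: dict[str, np.ndarray] = {"region_id": region_ids}
    handled: set[str] = set()

    def col(name: str) -> np.ndarray:
        return data.column(name)

    # region / country / migration ------------------------------------------
    if "region" in data:
        reg_levels = data.variable("region").levels
        uniq = np.unique(region_ids)
        country_of_region = {}
        for rid in uniq:
            rows = np.nonzero(region_ids == rid)[0]
            label = reg_levels[col("region")[rows[0]]]
            pool = COUNTRIES_BY_REGION.get(label, ALL_COUNTRIES)
            country_of_region[rid] = pool[int(rng.integers(len(pool)))]
        country = np.array([country_of_region[r] for r in region_ids], dtype=object)
        raw["country_iso"] = country
        handled.add("region")
        if "eu_migration" in data:
            mig = col("eu_migration")
            nat = country.copy()
            for i in np.nonzero(mig == 1)[0]:
                others = [c for c in ALL_COUNTRIES if c != country[i]]
                nat[i] = others[int(rng.integers(len(others)))]
            raw["nationality_iso"] = nat
            handled.add("eu_migration")

    if "sex" in data:
        raw["sex"] = (col("sex") + 1).astype(np.int64)  # 1=female, 2=male
        handled.add("sex")
    if "age_group" in data:
        levels = data.variable("age_group").levels
        age = np.empty(n, dtype=np.int64)
        for code, label in enumerate(levels):
            lo, hi = _AGE_RANGES[label]
            mask = col("age_group") == code
            age[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
        raw["age"] = age
        handled.add("age_group")

    if "sitting" in data:
        bands = {0: [1, 2, 3], 1: [4, 5], 2: [6, 7, 8], 3: [9, 10]}
        raw["sitting_10cat"] = _pick(bands, col("sitting"), rng).astype(np.int64)
        handled.add("sitting")

    if "pa" in data:
        pa = col("pa")
        mpa = np.zeros(n, dtype=np.int64)
        vpa = np.zeros(n, dtype=np.int64)
        low = pa == 1
        mpa[low] = rng.integers(1, 15, size=int(low.sum())) * 10  # 10..140
        vpa[low] = rng.integers(0, 8, size=int(low.sum())) * 10  # 0..70
        suf = pa == 2
        branch = rng.random(int(suf.sum())) < 0.5
        idx = np.nonzero(suf)[0]
        mpa[idx[branch]] = rng.integers(15, 40, size=int(branch.sum())) * 10
        vpa[idx[branch]] = rng.integers(0, 8, size=int(branch.sum())) * 10
        mpa[idx[~branch]] = rng.integers(0, 15, size=int((~branch).sum())) * 10
        vpa[idx[~branch]] = rng.integers(8, 21, size=int((~branch).sum())) * 10
        high = pa == 3
        mpa[high] = rng.integers(15, 40, size=int(high.sum())) * 10
        vpa[high] = rng.integers(8, 21, size=int(high.sum())) * 10
        raw["mpa_minutes"] = mpa
        raw["vpa_minutes"] = vpa
        handled.add("pa")

    if "life_satisfaction" in data:
        raw["life_satisfaction_4"] = _pick(
            {1: [1, 2], 0: [3, 4]}, col("life_satisfaction"), rng
        ).astype(np.int64)
        handled.add("life_satisfaction")

    if "netuse" in data:
        # raw 6-cat codes: 1-3 collapse to daily(2), 4-5 to monthly(1), 6 to never(0)
        level = col("netuse")
        reps = {2: [1, 2, 3], 1: [4, 5], 0: [6]}
        at_most = {2: [1, 2, 3, 4, 5, 6], 1: [4, 5, 6], 0: [6]}
        main = _pick(reps, level, rng).astype(np.int64)
        loc = rng.integers(0, 3, size=n)
        cols = []
        for j, name in enumerate(["netuse_home_6", "netuse_work_6", "netuse_else_6"]):
            vals = _pick(at_most, level, rng).astype(np.int64)
            vals[loc == j] = main[loc == j]
            raw[name] = vals
            cols.append(name)
        handled.add("netuse")

    if "occupation" in data:
        pre: dict[int, list] = {i: [] for i in range(8)}
        for raw_code, cat in OCC18_TO_8.items():
            pre[cat - 1].append(raw_code)
        raw["occupation_18"] = _pick(pre, col("occupation"), rng).astype(np.int64)
        handled.add("occupation")

    if "education" in data:
        ranges = {0: list(range(10, 16)), 1: list(range(16, 20)), 2: list(range(20, 31))}
        raw["education_stop_age"] = _pick(ranges, col("education"), rng).astype(np.int64)
        handled.add("education")

    if "social_class" in data:
        raw["social_class_3"] = _pick({0: [1], 1: [2, 3]}, col("social_class"), rng).astype(np.int64)
        handled.add("social_class")
    if "financial_burden" in data:
        raw["financial_burden_3"] = _pick(
            {1: [1, 2], 0: [3]}, col("financial_burden"), rng
        ).astype(np.int64)
        handled.add("financial_burden")
    if "wealth" in data:
        w = col("wealth")
        raw["own_home_paid"] = (w == 2).astype(np.int64)
        raw["own_home_paying"] = (w == 1).astype(np.int64)
        handled.add("wealth")
    for var, field in [("computer", "own_computer"), ("internet", "own_internet"),
                       ("car", "own_car")]:
        if var in data:
            raw[field] = col(var).astype(np.int64)
            handled.add(var)

    if "healthcare_quality" in data:
        raw["healthcare_quality_4"] = _pick(
            {1: [1, 2], 0: [3, 4]}, col("healthcare_quality"), rng
        ).astype(np.int64)
        handled.add("healthcare_quality")
    if "urbanity" in data:
        raw["urbanity_3"] = (col("urbanity") + 1).astype(np.int64)
        handled.add("urbanity")
    if "facility" in data:
        f = col("facility")
        item1 = _pick({1: [1, 2], 0: [3, 4]}, f, rng).astype(np.int64)
        item2 = np.where(
            f == 1,
            rng.integers(1, 5, size=n),
            _pick({0: [3, 4], 1: [3, 4]}, f, rng).astype(np.int64),
        )
        raw["facility_item1_4"] = item1
        raw["facility_item2_4"] = item2
        handled.add("facility")
    if "municipality" in data:
        # negative statement: agreement (1,2) means LOW perceived support
        raw["municipality_item_4"] = _pick(
            {0: [1, 2], 1: [3, 4]}, col("municipality"), rng
        ).astype(np.int64)
        handled.add("municipality")

    if "partner" in data and "children" in data:
        pre = {(p, c): [] for p in (0, 1) for c in (0, 1)}
        for code, flags in REL14_TO_FLAGS.items():
            pre[flags].append(code)
        rel = np.empty(n, dtype=np.int64)
        for (p, c), codes14 in pre.items():
            mask = (col("partner") == p) & (col("children") == c)
            k = int(mask.sum())
            if k:
                rel[mask] = rng.choice(codes14, size=k)
        raw["relationship_14"] = rel
        handled.update(["partner", "children"])

    if "household_size" in data:
        hh = col("household_size")
        total = np.zeros(n, dtype=np.int64)
        total[hh == 1] = 1
        total[hh == 2] = 2
        total[hh == 3] = rng.integers(3, 6, size=int((hh == 3).sum()))
        u10 = rng.binomial(total, 0.4)
        m10 = rng.binomial(total - u10, 0.3)
        raw["n_under10"] = u10
        raw["n_10to14"] = m10
        raw["n_15plus"] = total - u10 - m10
        handled.add("household_size")

    if "club_member" in data:
        member = col("club_member")
        masks = rng.integers(1, 16, size=n)  # non-zero 4-bit pattern
        for bit, name in enumerate(["club_health", "club_sport", "club_socio", "club_other"]):
            raw[name] = np.where(member == 1, (masks >> bit) & 1, 0).astype(np.int64)
        handled.add("club_member")

    # macro numeric fields: one value per region, copied to members ----------
    uniq = np.unique(region_ids) if n else np.array([], dtype=np.int64)
    inverse = {int(r): i for i, r in enumerate(uniq)}
    row_of_region = np.array([inverse[int(r)] for r in region_ids], dtype=np.int64) if n else None
    for var, ranges in _MACRO_NUMERIC_RANGES.items():
        if var not in data:
            continue
        levels = data.variable(var).levels
        vals = np.empty(len(uniq), dtype=float)
        for i, rid in enumerate(uniq):
            rows = np.nonzero(region_ids == rid)[0]
            label = levels[col(var)[rows[0]]]
            lo, hi = ranges[label]
            vals[i] = np.round(rng.uniform(lo, hi), 3)
        raw[_MACRO_RAW_NAMES[var]] = vals[row_of_region] if n else np.empty(0)
        handled.add(var)
    for var, field in [("sb_guidelines", "sb_guidelines_flag"),
                       ("pa_guidelines", "pa_guidelines_flag"),
                       ("transport_policy", "transport_policy_flag")]:
        if var in data:
            raw[field] = col(var).astype(np.int64)
            handled.add(var)

    # passthrough for schema variables without a raw decoder
    for var in data.schema:
        if var.name not in handled:
            raw[var.name] = col(var.name).astype(np.int64)

    return pd.DataFrame(raw)


def sample_dataset(model: GroundTruthModel, n: int, seed: int) -> pd.DataFrame:
    """Sample ``n`` respondents and expand them into a raw survey table."""
    data, region_ids = sample_categorical(model, n, seed, return_regions=True)
    return decode_to_raw(data, region_ids, seed)


# --------------------------------------------------------------------------- #
# missingness
# --------------------------------------------------------------------------- #

#: raw fields never masked: the MAR drivers and region bookkeeping
PROTECTED_FIELDS = ("sex", "age", "region_id", "country_iso")


def inject_missing(table: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Set cells to missing with a probability driven only by sex and age.

    The per-row missingness probability is a logistic function of the (always
    observed) sex and age fields, rescaled so the expected overall missing
    fraction equals ``rate`` — a missing-at-random mechanism by construction.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    out = table.copy()
    if rate == 0.0 or len(table) == 0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence([901223, int(seed)]))
    sex = table["sex"].to_numpy(dtype=float) if "sex" in table else np.ones(len(table))
    age = table["age"].to_numpy(dtype=float) if "age" in table else np.full(len(table), 40.0)
    band = np.digitize(age, [26, 45, 65])
    logit = -0.5 + 0.6 * (sex == 2).astype(float) + 0.3 * band
    w = 1.0 / (1.0 + np.exp(-logit))
    p_row = np.minimum(rate * w / w.mean(), 0.99)
    maskable = [c for c in out.columns if c not in PROTECTED_FIELDS]
    for c in maskable:
        hit = rng.random(len(out)) < p_row
        if hit.any():
            col = out[c]
            if pd.api.types.is_integer_dtype(col):
                out[c] = col.astype(float)
            out.loc[hit, c] = np.nan
    return out
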