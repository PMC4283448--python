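"""Synthetic amplicon communities on a two-transect deep-sea sampling design.

The generator emulates a sampling layout of 13 stations on two intersecting
transects — a bathymetric one (HGI–HGVI, 1284–3535 m water depth) and a
latitudinal one (N4…N1, HGIV, S1…S3 at ~2500 m) sharing the central station
HGIV — together with sediment environmental variables (CPE pigment,
porosity, particulate protein) and UTM coordinates.  Communities are built
OTU by OTU: a random base sequence receives planted sub-populations that
differ at a few variant alignment positions, each sub-population follows a
site-abundance scenario (log-linear in depth or CPE, checkerboard pair,
aggregated block, or neutral), and per-base substitution errors are applied
last.  Everything is returned together with its ground truth so downstream
recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from oligoscope.oligotyping import AlignedReadSet, CANONICAL_SITE_ORDER


class InvalidDesignError(ValueError):
    """Raised when a simulation design is internally inconsistent."""


#: Ranges of the environmental/spatial variables (study-area values).
ENV_RANGES = {
    "depth": (1284.0, 3535.0),  # m
    "cpe": (18.86, 44.26),  # µg cm^-3
    "porosity": (51.8, 72.3),  # % volume
    "easting": (512100.0, 565125.0),  # m (UTM)
    "northing": (8727035.0, 8850377.0),  # m (UTM)
}

SCENARIOS = (
    "depth_linear",
    "cpe_linked",
    "checkerboard_pair",
    "aggregated_block",
    "neutral",
)

# plausible deep-sea sediment lineages used to label synthetic OTUs
_TAXA = (
    ("Acidobacteria", "Acidobacteria", "Acidobacteriales"),
    ("Acidobacteria", "Subgroup 22", "-"),
    ("Actinobacteria", "Acidimicrobiia", "Acidimicrobiales"),
    ("Bacteroidetes", "Flavobacteria", "Flavobacteriales"),
    ("Bacteroidetes", "Cytophagia", "Cytophagales"),
    ("Gemmatimonadetes", "Gemmatimonadetes", "Gemmatimonadales"),
    ("Planctomycetes", "Planctomycetacia", "Planctomycetales"),
    ("Proteobacteria", "Alphaproteobacteria", "Rhodospirillales"),
    ("Proteobacteria", "Deltaproteobacteria", "Bdellovibrionales"),
    ("Proteobacteria", "Gammaproteobacteria", "Xanthomonadales"),
    ("Proteobacteria", "Gammaproteobacteria", "Incertae Sedis"),
    ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales"),
    ("Candidate division WS3", "-", "-"),
)


def _site_names(n_bath: int, n_lat_only: int) -> tuple[list[str], list[str]]:
    """Bathymetric station names and latitudinal-only station names."""
    if n_bath == 6 and n_lat_only == 7:
        bath = list(CANONICAL_SITE_ORDER[:6])
        lat = list(CANONICAL_SITE_ORDER[6:])
        return bath, lat
    bath = [f"HG{i + 1}" for i in range(n_bath)]
    n_north = (n_lat_only + 1) // 2
    lat = [f"N{n_north - i}" for i in range(n_north)]
    lat += [f"S{i + 1}" for i in range(n_lat_only - n_north)]
    return bath, lat


def generate_env_table(n_sites: int = 13, seed: int = 0) -> pd.DataFrame:
    """Generate the site × environment table for the two-transect design.

    Bathymetric stations have monotonically increasing depth spanning the
    full study range; latitudinal stations sit near 2500 m.  CPE decreases
    linearly with depth (plus small noise), porosity increases with depth,
    and particulate protein tracks CPE.  The central bathymetric station
    belongs to both transects.  Deterministic for a fixed seed.

    Returns a DataFrame indexed by site_id with columns depth, cpe,
    porosity, protein, easting, northing, transect, on_bathymetric,
    on_latitudinal.
    """
    if n_sites < 4:
        raise InvalidDesignError("the two-transect design needs at least 4 sites")
    rng = np.random.default_rng(seed)
    n_bath = max(2, round(n_sites * 6 / 13))
    n_lat_only = n_sites - n_bath
    bath_names, lat_names = _site_names(n_bath, n_lat_only)
    shared = bath_names[min(3, n_bath - 1)]  # HGIV in the default layout

    d_lo, d_hi = ENV_RANGES["depth"]
    # monotone depths with jittered interior spacing, endpoints pinned
    interior = np.sort(rng.uniform(0.1, 0.9, size=n_bath - 2)) if n_bath > 2 else []
    frac = np.concatenate([[0.0], interior, [1.0]])
    depth_bath = d_lo + frac * (d_hi - d_lo)
    depth_lat = np.clip(rng.normal(2500.0, 60.0, size=n_lat_only), d_lo, d_hi)

    names = bath_names + lat_names
    depth = np.concatenate([depth_bath, depth_lat])

    c_lo, c_hi = ENV_RANGES["cpe"]
    z = (depth - d_lo) / (d_hi - d_lo)
    cpe = np.clip(c_hi - z * (c_hi - c_lo) + rng.normal(0, 1.2, depth.size), c_lo, c_hi)
    p_lo, p_hi = ENV_RANGES["porosity"]
    porosity = np.clip(
        p_lo + z * (p_hi - p_lo) + rng.normal(0, 1.5, depth.size), p_lo, p_hi
    )
    protein = np.round(0.4 * cpe + rng.normal(0, 1.0, depth.size) + 5.0, 3)

    e_lo, e_hi = ENV_RANGES["easting"]
    n_lo, n_hi = ENV_RANGES["northing"]
    n_mid = 0.5 * (n_lo + n_hi)
    # bathymetric transect runs east (shallow) to west (deep) at mid northing
    easting_bath = e_hi - frac * (e_hi - e_lo)
    northing_bath = np.full(n_bath, n_mid) + rng.normal(0, 2000.0, n_bath)
    shared_idx = bath_names.index(shared)
    # latitudinal transect runs north to south through the shared station
    northing_lat = np.linspace(n_hi, n_lo, n_lat_only + 1)
    northing_lat = np.delete(
        northing_lat, np.argmin(np.abs(northing_lat - northing_bath[shared_idx]))
    )
    easting_lat = np.full(n_lat_only, easting_bath[shared_idx]) + rng.normal(
        0, 1500.0, n_lat_only
    )
    easting = np.clip(np.concatenate([easting_bath, easting_lat]), e_lo, e_hi)
    northing = np.clip(np.concatenate([northing_bath, northing_lat]), n_lo, n_hi)

    transect = ["bathymetric"] * n_bath + ["latitudinal"] * n_lat_only
    table = pd.DataFrame(
        {
            "depth": np.round(depth, 1),
            "cpe": np.round(cpe, 2),
            "porosity": np.round(porosity, 1),
            "protein": protein,
            "easting": np.round(easting, 0),
            "northing": np.round(northing, 0),
            "transect": transect,
            "on_bathymetric": [True] * n_bath + [False] * n_lat_only,
            "on_latitudinal": [n == shared for n in bath_names]
            + [True] * n_lat_only,
        },
        index=pd.Index(names, name="site_id"),
    )
    return table


# ---------------------------------------------------------------------------
# community design


@dataclass
class CommunityDesign:
    """Parameters of a synthetic community.

    ``scenarios`` gives one occurrence scenario per OTU (cycled over
    :data:`SCENARIOS` when omitted); ``reads_per_otu`` and
    ``variant_positions_per_otu`` are inclusive ranges sampled per OTU.
    Sub-population counts are drawn 2 + Poisson(4), truncated to at most 31
    and to one sub-population per ~60 reads so every planted group is large
    enough to be resolved.
    """

    n_otus: int = 10
    n_sites: int = 13
    reads_per_otu: tuple[int, int] = (100, 3000)
    variant_positions_per_otu: tuple[int, int] = (1, 5)
    read_length: int = 400
    error_rate: float = 0.001
    missing_tail_fraction: float = 0.02
    scenarios: list[str] | None = None
    site_depth_multiplier: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 1 or self.n_sites < 1 or self.read_length < 1:
            raise InvalidDesignError("all counts must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise InvalidDesignError("error_rate must be in [0, 0.5)")
        if self.reads_per_otu[0] > self.reads_per_otu[1]:
            raise InvalidDesignError("reads_per_otu range is inverted")
        if self.scenarios is None:
            self.scenarios = [SCENARIOS[i % len(SCENARIOS)] for i in range(self.n_otus)]
        if len(self.scenarios) != self.n_otus:
            raise InvalidDesignError("scenario list length must equal n_otus")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise InvalidDesignError(f"unknown scenarios: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Planted structure of a generated community.

    ``assignments[otu_id]`` maps each read (row of the OTU's alignment) to
    its planted sub-population; ``subpop_info[otu_id]`` lists, per
    sub-population, the discriminant (position, character) pairs, the
    realised site-count profile and the generating coefficients;
    ``scenario_of[otu_id]`` names the occurrence scenario.
    """

    assignments: dict[str, np.ndarray] = field(default_factory=dict)
    subpop_info: dict[str, list[dict]] = field(default_factory=dict)
    scenario_of: dict[str, str] = field(default_factory=dict)
    variant_positions: dict[str, list[int]] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            otu: {
                "scenario": self.scenario_of[otu],
                "variant_positions": list(map(int, self.variant_positions[otu])),
                "assignments": self.assignments[otu].tolist(),
                "subpopulations": [
                    {
                        "discriminants": [
                            [int(p), c] for p, c in info["discriminants"]
                        ],
                        "profile": {s: int(v) for s, v in info["profile"].items()},
                        "coefficients": info["coefficients"],
                    }
                    for info in self.subpop_info[otu]
                ],
            }
            for otu in self.assignments
        }


_BASES = np.array(["A", "C", "G", "T"])
_VARIANT_CHARS = np.array(["A", "C", "G", "T", "-"])


def _subpop_chars(k: int, n_positions: int, rng: np.random.Generator) -> np.ndarray:
    """Character tuples (k × n_positions) separating k sub-populations.

    Positions act as mixed-radix digits so the recursive entropy splits can
    peel the sub-populations apart position by position; when a position is
    not needed to separate the groups it still carries distinct characters
    wherever possible, giving redundant discriminants.
    """
    chars = np.empty((k, n_positions), dtype="<U1")
    radix = 5
    for j in range(n_positions):
        digits = (np.arange(k) // (radix**j)) % radix
        perm = rng.permutation(5)
        chars[:, j] = _VARIANT_CHARS[perm[digits]]
    return chars


def _scenario_profiles(
    scenario: str,
    k: int,
    env: pd.DataFrame,
    total_reads: int,
    site_weight: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[dict]]:
    """Expected per-site read counts (k × n_sites) plus coefficients.

    Each sub-population's profile is normalised to an equal share of the
    OTU's reads so that planted groups stay comparably sized.
    """
    n_sites = env.shape[0]
    coefs: list[dict] = []
    weights = np.empty((k, n_sites))
    if scenario in ("depth_linear", "cpe_linked"):
        var = "depth" if scenario == "depth_linear" else "cpe"
        x = env[var].to_numpy(float)
        zx = (x - x.mean()) / x.std()
        for i in range(k):
            b = rng.uniform(0.6, 1.3) * (1 if i % 2 == 0 else -1)
            weights[i] = np.exp(b * zx)
            coefs.append({"variable": var, "slope": float(b)})
    elif scenario == "checkerboard_pair":
        # pairs of sub-populations occupy complementary site sets
        for i in range(0, k, 2):
            half = rng.permutation(n_sites)
            left, right = half[: n_sites // 2], half[n_sites // 2 :]
            w = np.zeros(n_sites)
            w[left] = 1.0
            weights[i] = w
            coefs.append({"support": sorted(map(int, left))})
            if i + 1 < k:
                w2 = np.zeros(n_sites)
                w2[right] = 1.0
                weights[i + 1] = w2
                coefs.append({"support": sorted(map(int, right))})
    elif scenario == "aggregated_block":
        block = rng.permutation(n_sites)[: max(2, n_sites // 2)]
        for i in range(k):
            w = np.zeros(n_sites)
            w[block] = rng.uniform(0.6, 1.4, size=block.size)
            weights[i] = w
            coefs.append({"support": sorted(map(int, block))})
    elif scenario == "neutral":
        for i in range(k):
            weights[i] = np.exp(rng.normal(0, 0.3, size=n_sites))
            coefs.append({})
    else:  # pragma: no cover - guarded by CommunityDesign
        raise InvalidDesignError(f"unknown scenario {scenario!r}")
    weights *= site_weight
    share = total_reads / k
    sums = weights.sum(axis=1, keepdims=True)
    return weights / sums * share, coefs


def generate_community(
    design: CommunityDesign, env: pd.DataFrame
) -> tuple[list[AlignedReadSet], GroundTruth]:
    """Generate per-OTU aligned read sets and their ground truth.

    Every OTU consists of one random base sequence; planted sub-populations
    differ only at the drawn variant positions (characters may include the
    internal gap ``-``).  Per-site counts are Poisson around the scenario's
    expectation.  A ``missing_tail_fraction`` of reads have their terminal
    segment replaced by the missing-coverage character ``.``; variant
    positions are drawn away from the tail region.
    """
    if env.shape[0] != design.n_sites:
        raise InvalidDesignError(
            f"env table has {env.shape[0]} sites, design expects {design.n_sites}"
        )
    rng = np.random.default_rng(design.seed)
    sites = env.index.to_numpy()
    if design.site_depth_multiplier:
        site_weight = np.array(
            [design.site_depth_multiplier.get(s, 1.0) for s in env.index]
        )
    else:
        site_weight = np.ones(design.n_sites)

    truth = GroundTruth()
    read_sets: list[AlignedReadSet] = []
    for o in range(design.n_otus):
        otu_id = f"OTU{o:04d}"
        scenario = design.scenarios[o]
        total = int(rng.integers(design.reads_per_otu[0], design.reads_per_otu[1] + 1))
        v_lo, v_hi = design.variant_positions_per_otu
        n_var = int(rng.integers(v_lo, v_hi + 1))
        # one sub-population per ~60 reads keeps groups resolvable
        k_cap = min(31, 5**n_var if n_var else 1, max(1, total // 60))
        if scenario == "checkerboard_pair":
            k = 2 if k_cap >= 2 else 1
        elif n_var == 0 or k_cap < 2:
            k = 1
        else:
            k = int(np.clip(2 + rng.poisson(4), 2, k_cap))

        base = rng.choice(_BASES, size=design.read_length)
        core = int(design.read_length * 0.9)  # tail reserved for '.' masking
        var_positions = (
            np.sort(rng.choice(core, size=min(n_var, core), replace=False))
            if n_var
            else np.array([], dtype=int)
        )
        chars = (
            _subpop_chars(k, var_positions.size, rng)
            if var_positions.size
            else np.empty((k, 0), dtype="<U1")
        )

        expected, coefs = _scenario_profiles(
            scenario, k, env, total, site_weight, rng
        )
        counts = rng.poisson(expected)  # k × n_sites realised reads

        rows, site_lab, assign = [], [], []
        for i in range(k):
            seq = base.copy()
            if var_positions.size:
                seq[var_positions] = chars[i]
            for s_idx, s in enumerate(sites):
                c = int(counts[i, s_idx])
                if c:
                    rows.append(np.tile(seq, (c, 1)))
                    site_lab.extend([s] * c)
                    assign.extend([i] * c)
        if not rows:  # degenerate draw: force one read so the OTU exists
            rows.append(base[None, :].copy())
            site_lab.append(sites[0])
            assign.append(0)
            counts[0, 0] += 1
        reads = np.concatenate(rows, axis=0)
        assign = np.asarray(assign)

        if design.error_rate > 0:
            reads = inject_errors(
                reads, design.error_rate, seed=int(rng.integers(2**31))
            )
        if design.missing_tail_fraction > 0:
            n_masked = int(round(reads.shape[0] * design.missing_tail_fraction))
            if n_masked:
                masked = rng.choice(reads.shape[0], size=n_masked, replace=False)
                starts = rng.integers(core, design.read_length, size=n_masked)
                for r, st in zip(masked, starts):
                    reads[r, st:] = "."

        taxonomy = dict(
            zip(("phylum", "class", "order"), _TAXA[int(rng.integers(len(_TAXA)))])
        )
        read_ids = np.array(
            [f"{otu_id}|{s}|{j}" for j, s in enumerate(site_lab)]
        )
        read_sets.append(
            AlignedReadSet(
                otu_id=otu_id,
                reads=reads,
                site_of_read=np.asarray(site_lab),
                read_ids=read_ids,
                taxonomy=taxonomy,
            )
        )
        truth.assignments[otu_id] = assign
        truth.scenario_of[otu_id] = scenario
        truth.variant_positions[otu_id] = list(map(int, var_positions))
        truth.subpop_info[otu_id] = [
            {
                "discriminants": [
                    (int(p), chars[i, j]) for j, p in enumerate(var_positions)
                ],
                "profile": {s: int(counts[i, s_idx]) for s_idx, s in enumerate(sites)},
                "coefficients": coefs[i],
            }
            for i in range(k)
        ]
    return read_sets, truth


def inject_errors(reads: np.ndarray, error_rate: float, seed: int = 0) -> np.ndarray:
    """Apply independent per-base substitution errors.

    Each ``A/C/G/T`` base is substituted with probability ``error_rate``,
    uniformly over the three alternative bases; gap (``-``) and missing
    (``.``) characters are never mutated.  Deterministic for a fixed seed;
    the input array is not modified.
    """
    if not 0.0 <= error_rate < 0.5:
        raise InvalidDesignError("error_rate must be in [0, 0.5)")
    reads = np.asarray(reads, dtype="<U1")
    out = reads.copy()
    if error_rate == 0.0 or reads.size == 0:
        return out
    rng = np.random.default_rng(seed)
    is_base = np.isin(reads, _BASES)
    hit = is_base & (rng.random(reads.shape) < error_rate)
    if not hit.any():
        return out
    # substitute by shifting 1..3 steps in the base cycle A->C->G->T->A
    base_index = np.zeros(reads.shape, dtype=int)
    for i, b in enumerate(_BASES):
        base_index[reads == b] = i
    shift = rng.integers(1, 4, size=int(hit.sum()))
    out[hit] = _BASES[(base_index[hit] + shift) % 4]
    return out
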