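"""Synthetic cohorts with the spatio-temporal structure the analysis assumes.

Three layers, each seeded and deterministic:

1. :func:`simulate_cohort` — draws per-sample metadata (region, birth year,
   metropolitan flag) and a *true* haplogroup from a region- and year-adjusted
   frequency vector (:class:`FrequencyModel`).
2. :func:`simulate_genotypes` — converts each true haplogroup into the haploid
   genotype implied by its root→node path through a haplogroup tree (derived
   allele at every defining variant on the path, ancestral elsewhere), then
   adds private mutations and missingness.
3. :func:`simulate_intensities` — inverts the array caller: emits (Norm R,
   Norm Theta) intensity pairs whose cluster geometry reproduces the calls.

:func:`denmark_model` builds the default :class:`FrequencyModel` from the
published regional and temporal tallies of the Danish birth cohort
(:mod:`mitocline.danish_cohort`): regional haplogroup frequencies follow the
five-region table, and haplogroups L (aggregate), M and U carry additive
per-year trends chosen so the simulated 1981-1986 and 2000-2005 period means
match the printed period frequencies (L 0.2%→1.2%, M 1.0%→2.4%, U 12.7%→14.3%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import danish_cohort as dk
from .matrix import ALT, MISSING, REF, GenotypeMatrix
from .tree import HaploTree

__all__ = [
    "ConfigError",
    "FrequencyModel",
    "denmark_model",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_intensities",
    "true_calls",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class FrequencyModel:
    """Haplogroup frequencies by region with additive per-year trends.

    ``base_freq[region][hg]`` is the proportion of haplogroup ``hg`` in
    ``region`` at the first year of ``years``; ``trend[hg]`` is an additive
    per-year change applied uniformly across regions. Realized vectors are
    clipped at zero and renormalized so they stay simplex-valued.
    """

    regions: list[str]
    years: tuple[int, int]
    base_freq: dict[str, dict[str, float]]
    trend: dict[str, float] = field(default_factory=dict)
    region_weights: dict[str, float] = field(default_factory=dict)
    metro_flag_freq: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.years[0] > self.years[1]:
            raise ConfigError(f"invalid year range {self.years}")
        missing = [r for r in self.regions if r not in self.base_freq]
        if missing:
            raise ConfigError(f"regions without base frequencies: {missing}")
        if not self.region_weights:
            self.region_weights = {r: 1.0 for r in self.regions}
        if not self.metro_flag_freq:
            self.metro_flag_freq = {r: 0.0 for r in self.regions}
        for region in self.regions:
            freqs = self.base_freq[region]
            if any(p < 0 for p in freqs.values()):
                raise ConfigError(f"negative base frequency in region {region}")
            total = sum(freqs.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ConfigError(
                    f"base frequencies in region {region} sum to {total:.6f}, not 1"
                )

    @property
    def haplogroups(self) -> list[str]:
        labels: set[str] = set()
        for freqs in self.base_freq.values():
            labels.update(freqs)
        labels.update(self.trend)
        return sorted(labels)

    def validate_tree(self, tree: HaploTree) -> None:
        unknown = [h for h in self.haplogroups if h not in tree]
        if unknown:
            raise ConfigError(
                f"haplogroup labels not present in the tree: {unknown}"
            )

    def freq_vector(self, region: str, year: int) -> pd.Series:
        """Realized frequency vector for one region-year stratum (sums to 1)."""
        if region not in self.base_freq:
            raise ConfigError(f"unknown region {region!r}")
        if not self.years[0] <= year <= self.years[1]:
            raise ConfigError(f"year {year} outside configured range {self.years}")
        dt = year - self.years[0]
        labels = self.haplogroups
        p = np.array(
            [
                self.base_freq[region].get(h, 0.0) + dt * self.trend.get(h, 0.0)
                for h in labels
            ]
        )
        p = np.clip(p, 0.0, None)
        total = p.sum()
        if total <= 0:
            raise ConfigError(f"degenerate frequency vector for {region}/{year}")
        return pd.Series(p / total, index=labels)

    # -- YAML round-trip ---------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "regions": list(self.regions),
            "years": [int(self.years[0]), int(self.years[1])],
            "base_freq": {
                r: {h: float(p) for h, p in freqs.items()}
                for r, freqs in self.base_freq.items()
            },
            "trend": {h: float(t) for h, t in self.trend.items()},
            "region_weights": {r: float(w) for r, w in self.region_weights.items()},
            "metro_flag_freq": {r: float(f) for r, f in self.metro_flag_freq.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "FrequencyModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            regions=list(doc["regions"]),
            years=tuple(doc["years"]),
            base_freq=doc["base_freq"],
            trend=doc.get("trend", {}),
            region_weights=doc.get("region_weights", {}),
            metro_flag_freq=doc.get("metro_flag_freq", {}),
        )


def _split(total: float, parts: dict[str, int]) -> dict[str, float]:
    """Split a proportion across labels by integer-count weights."""
    denom = sum(parts.values())
    return {k: total * v / denom for k, v in parts.items() if v > 0}


# Default within-region metropolitan sampling fractions. The survey does not
# publish them; these reflect which regions contain the four major cities
# (Copenhagen/Capital, Aarhus/Central, Odense/South, Aalborg/North).
_DEFAULT_METRO = {
    "Capital": 0.75,
    "Zealand": 0.10,
    "Central": 0.35,
    "South": 0.25,
    "North": 0.30,
}


def denmark_model() -> FrequencyModel:
    """Default frequency model calibrated to the published Danish tallies.

    The published regional rows mix reporting levels (haplogroup bins for most
    rows, whole macro-haplogroups for L and M). The model resolves each row to
    concrete tree nodes: H/U/J/K/T are split into their sub-haplogroups and L
    and M into their constituent clades, proportional to the published
    within-clade distributions, so that simulated cohorts exercise all three
    classification levels. Trends are split across constituent nodes in
    proportion to their base share.
    """
    y0, y1 = 1981, 2005
    span = (2000 + 2005) / 2 - (1981 + 1986) / 2  # 19 years between period midpoints
    n1, n2 = dk.PERIOD_TOTALS

    # National per-year additive trends for the rows that changed over time.
    trend_rows = {
        h: (dk.PERIOD_COUNTS[h][1] / n2 - dk.PERIOD_COUNTS[h][0] / n1) / span
        for h in ("L", "M", "U")
    }

    # How each published regional row maps onto tree nodes.
    row_nodes: dict[str, dict[str, int]] = {
        "H": {
            "H": dk.SUBHG_COUNTS["H"]["H"],
            "H1": dk.SUBHG_COUNTS["H"]["H1-H30b-H79a"],
            "H2": dk.SUBHG_COUNTS["H"]["H2"],
            "H3": dk.SUBHG_COUNTS["H"]["H3"],
            "H4": dk.SUBHG_COUNTS["H"]["H4"],
            "H5": dk.SUBHG_COUNTS["H"]["H5-36"],
        },
        "U": {
            "U": dk.SUBHG_COUNTS["U"]["U"],
            "U1": dk.SUBHG_COUNTS["U"]["U1"],
            "U2": dk.SUBHG_COUNTS["U"]["U2-U3"] // 2,
            "U3": dk.SUBHG_COUNTS["U"]["U2-U3"] - dk.SUBHG_COUNTS["U"]["U2-U3"] // 2,
            "U4": dk.SUBHG_COUNTS["U"]["U4-9"] // 2,
            "U9": dk.SUBHG_COUNTS["U"]["U4-9"] - dk.SUBHG_COUNTS["U"]["U4-9"] // 2,
            "U5a": dk.SUBHG_COUNTS["U"]["U5a"],
            "U5b": dk.SUBHG_COUNTS["U"]["U5b"],
            "U6": dk.SUBHG_COUNTS["U"]["U6"],
            "U7": dk.SUBHG_COUNTS["U"]["U7"],
            "U8": dk.SUBHG_COUNTS["U"]["U8"],
        },
        "J": {"J": dk.SUBHG_COUNTS["J"]["J"], "J1": dk.SUBHG_COUNTS["J"]["J1"],
              "J2": dk.SUBHG_COUNTS["J"]["J2"]},
        "K": {"K": dk.SUBHG_COUNTS["K"]["K"], "K1": dk.SUBHG_COUNTS["K"]["K1"],
              "K2": dk.SUBHG_COUNTS["K"]["K2"], "K3": dk.SUBHG_COUNTS["K"]["K3"]},
        "T": {"T": dk.SUBHG_COUNTS["T"]["T*"], "T1": dk.SUBHG_COUNTS["T"]["T1"],
              "T2": dk.SUBHG_COUNTS["T"]["T2"]},
        "L": {h: n for h, n in dk.MACRO_COUNTS.items() if h.startswith("L") and n > 0},
        "M": dk.M_HG_COUNTS,
        "I": {"I": 1},
        "N": {"N": 1},
        "R": {"R": 1},
        "V": {"V": 1},
        "W": {"W": 1},
        "X": {"X": 1},
    }

    # Trended rows are anchored multiplicatively: the published regional value
    # is a whole-period (1981-2005) mean, 12 years of trend past the base
    # year, so every region's base is the published value scaled by the
    # national base/mean ratio. This keeps regional enrichment ratios intact
    # and avoids clipping small regional frequencies at zero.
    nat_total = sum(dk.REGIONAL_TOTALS.values())
    base_scale = {}
    for row, t_row in trend_rows.items():
        nat_mean = sum(dk.REGIONAL_COUNTS[row]) / nat_total
        base_scale[row] = max(0.0, 1.0 - 12.0 * t_row / nat_mean)

    base_freq: dict[str, dict[str, float]] = {}
    for ri, region in enumerate(dk.REGIONS):
        total = dk.REGIONAL_TOTALS[region]
        freqs: dict[str, float] = {}
        for row, counts in dk.REGIONAL_COUNTS.items():
            if row == "NA":
                continue  # unassignable samples arise from noise, not frequency
            p_row = counts[ri] / total * base_scale.get(row, 1.0)
            for node, p in _split(p_row, row_nodes[row]).items():
                freqs[node] = freqs.get(node, 0.0) + p
        norm = sum(freqs.values())
        base_freq[region] = {h: p / norm for h, p in freqs.items()}

    # National trend split across constituent nodes by within-row share.
    trend: dict[str, float] = {}
    for row, t_row in trend_rows.items():
        for node, share in _split(1.0, row_nodes[row]).items():
            trend[node] = trend.get(node, 0.0) + t_row * share

    return FrequencyModel(
        regions=list(dk.REGIONS),
        years=(y0, y1),
        base_freq=base_freq,
        trend=trend,
        region_weights={r: float(dk.REGIONAL_TOTALS[r]) for r in dk.REGIONS},
        metro_flag_freq=dict(_DEFAULT_METRO),
    )


def simulate_cohort(
    model: FrequencyModel, tree: HaploTree, n: int, seed: int
) -> pd.DataFrame:
    """Draw ``n`` independent samples from the frequency model.

    Returns a cohort table with columns ``sample_id``, ``birth_year``,
    ``region``, ``metro``, ``true_hg``. Identical ``(model, n, seed)`` give
    bit-identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model.validate_tree(tree)
    rng = np.random.default_rng(seed)

    regions = list(model.regions)
    w = np.array([model.region_weights[r] for r in regions], dtype=float)
    region_idx = rng.choice(len(regions), size=n, p=w / w.sum())
    years = rng.integers(model.years[0], model.years[1] + 1, size=n)
    metro_p = np.array([model.metro_flag_freq[r] for r in regions])
    metro = rng.random(n) < metro_p[region_idx]

    labels = model.haplogroups
    # Cumulative frequency row per (region, year) stratum; one uniform draw
    # per sample inverted against its stratum's CDF.
    n_years = model.years[1] - model.years[0] + 1
    cum = np.empty((len(regions), n_years, len(labels)))
    for ri, region in enumerate(regions):
        for yi in range(n_years):
            cum[ri, yi] = np.cumsum(
                model.freq_vector(region, model.years[0] + yi).to_numpy()
            )
    u = rng.random(n)
    rows = cum[region_idx, years - model.years[0]]
    hg_idx = (u[:, None] > rows).sum(axis=1)
    true_hg = [labels[i] for i in hg_idx]

    return pd.DataFrame(
        {
            "sample_id": [f"S{i:06d}" for i in range(n)],
            "birth_year": years.astype(int),
            "region": [regions[i] for i in region_idx],
            "metro": metro,
            "true_hg": true_hg,
        }
    )


def simulate_genotypes(
    cohort: pd.DataFrame,
    tree: HaploTree,
    panel: pd.DataFrame,
    private_mut_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Genotypes implied by each sample's true haplogroup path, plus noise.

    Each sample carries the derived (ALT) allele at every defining variant on
    its root→true_hg path and the ancestral (REF) allele elsewhere. Private
    mutations then flip non-path loci independently at ``private_mut_rate``
    (never the sample's own defining positions, which keeps classification
    identifiable), and calls are masked to MISSING at ``missing_rate``.
    """
    for name, rate in (("private_mut_rate", private_mut_rate),
                       ("missing_rate", missing_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pos_to_idx = {int(p): i for i, p in enumerate(panel["position"])}
    alt = {int(p): a for p, a in zip(panel["position"], panel["alt"])}
    n_loci = len(panel)

    path_haplotype: dict[str, np.ndarray] = {}
    path_cols: dict[str, np.ndarray] = {}
    for hg in sorted(set(cohort["true_hg"])):
        if hg not in tree:
            raise ConfigError(f"unknown haplogroup label {hg!r} in cohort")
        hap = np.zeros(n_loci, dtype=np.int8)
        cols = []
        for node_name in tree.path_to(hg):
            for v in tree.nodes[node_name].variants:
                if v.position not in pos_to_idx or alt[v.position] != v.allele:
                    raise ConfigError(
                        f"panel lacks defining variant {v.position}:{v.allele} "
                        f"of node {node_name}"
                    )
                hap[pos_to_idx[v.position]] = ALT
                cols.append(pos_to_idx[v.position])
        path_haplotype[hg] = hap
        path_cols[hg] = np.array(sorted(set(cols)), dtype=int)

    n = len(cohort)
    calls = np.empty((n, n_loci), dtype=np.int8)
    for i, hg in enumerate(cohort["true_hg"]):
        calls[i] = path_haplotype[hg]

    if private_mut_rate > 0:
        flips = rng.random((n, n_loci)) < private_mut_rate
        for i, hg in enumerate(cohort["true_hg"]):
            flips[i, path_cols[hg]] = False
        calls = np.where(flips, (calls == REF).astype(np.int8), calls)

    if missing_rate > 0:
        mask = rng.random((n, n_loci)) < missing_rate
        calls[mask] = MISSING

    return GenotypeMatrix(list(cohort["sample_id"]), panel.reset_index(drop=True), calls)


def simulate_intensities(
    genotypes: GenotypeMatrix,
    noise_sd: float = 0.0,
    lowintensity_rate: float = 0.0,
    ab_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Array intensity records (sample_id, position, r, theta) for the caller.

    Cluster geometry: REF calls draw theta from a clipped Gaussian around 0.05
    and ALT around 0.95 (sd = ``noise_sd``); a fraction ``ab_rate`` of records
    is relocated into the heteroplasmic AB band (theta near 0.5); a fraction
    ``lowintensity_rate`` receives Norm R below the 0.08 rejection threshold,
    all other records r >= 0.08. MISSING input calls always emit low-intensity
    records so that calling them round-trips to MISSING.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for name, rate in (("lowintensity_rate", lowintensity_rate), ("ab_rate", ab_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n, L = genotypes.calls.shape
    calls = genotypes.calls.ravel()
    size = n * L

    center = np.where(calls == ALT, 0.95, 0.05)
    theta = np.clip(center + rng.normal(0.0, noise_sd or 0.0, size=size), 0.0, 1.0)
    ab = rng.random(size) < ab_rate
    theta[ab] = rng.uniform(0.40, 0.60, size=int(ab.sum()))

    low = rng.random(size) < lowintensity_rate
    low |= calls == MISSING
    r = rng.uniform(0.20, 2.00, size=size)
    r[low] = rng.uniform(0.0, 0.0799, size=int(low.sum()))

    positions = np.tile(genotypes.loci["position"].to_numpy(), n)
    sample_ids = np.repeat(np.asarray(genotypes.sample_ids, dtype=object), L)
    return pd.DataFrame(
        {"sample_id": sample_ids, "position": positions, "r": r, "theta": theta}
    )


def true_calls(cohort: pd.DataFrame, tree: HaploTree) -> list:
    """Oracle classifications from the simulated truth column.

    Expands each sample's ``true_hg`` into per-level labels by walking its
    tree path — the ground truth against which classifier output and
    frequency statistics are checked.
    """
    from .classify import UNASSIGNED, HgCall

    out = []
    for sid, hg in zip(cohort["sample_id"], cohort["true_hg"]):
        call = HgCall(sample_id=sid, status="full")
        for level in ("macro", "hg", "subhg"):
            anc = tree.ancestor_at_level(hg, level)
            if anc is None:
                anc = UNASSIGNED
            if level == "macro":
                call.macro_hg = anc
            elif level == "hg":
                call.hg = anc
            else:
                call.sub_hg = anc
        out.append(call)
    return out
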