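"""Array-intensity genotype calling for haploid mtDNA loci.

Calls are made from normalized intensity (Norm R) and allele angle (Norm
Theta): records with R below an intensity floor are unreliable and rejected;
remaining records are assigned to the REF (AA) or ALT (BB) theta cluster, and
records falling in the heteroplasmic AB band between the clusters are treated
as missing. Sample-level QC removes samples whose call rate falls below a
threshold (default 97%).

The published pipeline adjusted theta cluster boundaries manually per locus;
here a fixed symmetric band (0.25/0.75) is the reproducible default, with
optional per-locus overrides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ALT, MISSING, REF, GenotypeMatrix

__all__ = ["CallerThresholds", "call_genotype", "call_matrix", "sample_qc"]


@dataclass(frozen=True)
class CallerThresholds:
    """Intensity and cluster thresholds for haploid calling.

    min_r: Norm R floor; records below it are rejected (default 0.08).
    theta_ref_max / theta_alt_min: REF/ALT cluster boundaries; theta strictly
        between them is the AB band and called MISSING.
    min_sample_call_rate: QC floor on per-sample call rate (default 0.97).
    per_locus: optional {position: (theta_ref_max, theta_alt_min)} overrides.
    """

    min_r: float = 0.08
    theta_ref_max: float = 0.25
    theta_alt_min: float = 0.75
    min_sample_call_rate: float = 0.97
    per_locus: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.min_r < 0:
            raise ValueError("min_r must be >= 0")
        if not self.theta_ref_max < self.theta_alt_min:
            raise ValueError("theta_ref_max must be < theta_alt_min")
        if not 0 < self.min_sample_call_rate <= 1:
            raise ValueError("min_sample_call_rate must be in (0, 1]")
        for pos, (lo, hi) in self.per_locus.items():
            if not lo < hi:
                raise ValueError(f"per-locus band at {pos} must satisfy lo < hi")


def call_genotype(r: float, theta: float, t: CallerThresholds, position: int | None = None):
    """Call a single intensity record: REF, ALT or MISSING (int8 codes)."""
    lo, hi = t.per_locus.get(position, (t.theta_ref_max, t.theta_alt_min))
    if r < t.min_r:
        return MISSING
    if theta <= lo:
        return REF
    if theta >= hi:
        return ALT
    return MISSING


def call_matrix(
    records: pd.DataFrame,
    loci: pd.DataFrame,
    t: CallerThresholds,
    sample_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Call a full samples x loci matrix from intensity records.

    ``records`` has columns sample_id, position, r, theta; (sample, locus)
    pairs without a record are MISSING. ``sample_ids`` fixes the sample set
    and row order; by default it is the sorted set observed in ``records``.
    Records at positions absent from ``loci`` raise a ValueError.
    """
    pos_to_idx = {int(p): i for i, p in enumerate(loci["position"])}
    if sample_ids is None:
        sample_ids = sorted(set(records["sample_id"]))
    sid_to_row = {s: i for i, s in enumerate(sample_ids)}
    n, L = len(sample_ids), len(loci)
    calls = np.full((n, L), MISSING, dtype=np.int8)
    if len(records):
        positions = records["position"].to_numpy()
        unknown = sorted(set(int(p) for p in positions) - set(pos_to_idx))
        if unknown:
            raise ValueError(f"records at positions not in the panel: {unknown}")
        cols = np.array([pos_to_idx[int(p)] for p in positions])
        rows = np.array([sid_to_row[s] for s in records["sample_id"]])
        r = records["r"].to_numpy(dtype=float)
        theta = records["theta"].to_numpy(dtype=float)

        lo = np.full(L, t.theta_ref_max)
        hi = np.full(L, t.theta_alt_min)
        for pos, (plo, phi) in t.per_locus.items():
            if pos in pos_to_idx:
                lo[pos_to_idx[pos]] = plo
                hi[pos_to_idx[pos]] = phi
        vals = np.full(len(records), MISSING, dtype=np.int8)
        ok = r >= t.min_r
        vals[ok & (theta <= lo[cols])] = REF
        vals[ok & (theta >= hi[cols])] = ALT
        calls[rows, cols] = vals
    return GenotypeMatrix(list(sample_ids), loci.reset_index(drop=True), calls)


def sample_qc(
    g: GenotypeMatrix, t: CallerThresholds
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop samples below the call-rate floor.

    Returns the kept matrix and a report of removed samples with their call
    rates. Idempotent: the kept matrix passes QC unchanged.
    """
    if g.n_samples == 0:
        raise ValueError("empty genotype matrix")
    rates = g.call_rates()
    keep = rates >= t.min_sample_call_rate
    report = pd.DataFrame(
        {
            "sample_id": [s for s, k in zip(g.sample_ids, keep) if not k],
            "call_rate": rates[~keep],
        }
    ).reset_index(drop=True)
    return g.subset_samples(keep), report
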