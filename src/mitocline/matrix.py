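"""Haploid genotype matrix over {REF, ALT, MISSING} and panel construction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["REF", "ALT", "MISSING", "GenotypeMatrix", "default_panel"]

REF = np.int8(0)
ALT = np.int8(1)
MISSING = np.int8(-1)


@dataclass
class GenotypeMatrix:
    """Samples x loci haploid call matrix.

    ``calls`` holds int8 codes REF=0, ALT=1, MISSING=-1. ``loci`` is a
    DataFrame with columns ``position`` (1-based rCRS, unique), ``ref``,
    ``alt`` and defines the column order of ``calls``.
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        pos = self.loci["position"].to_numpy()
        if len(np.unique(pos)) != len(pos):
            raise ValueError("locus positions must be unique")
        if not np.isin(self.calls, [REF, ALT, MISSING]).all():
            raise ValueError("calls must be in {0, 1, -1}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def call_rates(self) -> np.ndarray:
        """Per-sample fraction of non-missing calls."""
        return (self.calls != MISSING).mean(axis=1)

    def position_index(self) -> dict[int, int]:
        return {int(p): i for i, p in enumerate(self.loci["position"])}

    def subset_samples(self, keep: np.ndarray | list[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in keep],
            self.loci.reset_index(drop=True),
            self.calls[keep].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids), self.loci.copy(), self.calls.copy()
        )


def default_panel(tree, n_loci: int = 418) -> pd.DataFrame:
    """Build a deterministic genotyping panel covering a haplogroup tree.

    All defining positions of ``tree`` are included with the derived allele as
    ALT; remaining slots are filled with evenly spaced non-defining positions
    across the 16,569 bp rCRS circle (C→T by convention). The default size of
    418 loci matches common psychiatric-array mtDNA content.
    """
    defining: dict[int, str] = {}
    for node in tree.nodes.values():
        for v in node.variants:
            defining[v.position] = v.allele
    if len(defining) > n_loci:
        raise ValueError(
            f"tree has {len(defining)} defining positions, more than n_loci={n_loci}"
        )
    positions = sorted(defining)
    n_fill = n_loci - len(positions)
    filler: list[int] = []
    step = 16569 / max(n_fill * 2, 1)
    cand = 1.0
    while len(filler) < n_fill:
        p = int(round(cand)) % 16569 + 1
        if p not in defining and p not in filler:
            filler.append(p)
        cand += step
    rows = []
    for p in sorted(positions + filler):
        if p in defining:
            derived = defining[p]
            ref = "A" if derived != "A" else "G"
            rows.append((p, ref, derived))
        else:
            rows.append((p, "C", "T"))
    return pd.DataFrame(rows, columns=["position", "ref", "alt"])
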