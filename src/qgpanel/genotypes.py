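"""In-memory genotype container shared by every stage of the pipeline.

Genotypes are biallelic SNP dosages for (mostly) fully inbred lines: entries
0/2 for the two homozygotes, 1 for residual heterozygous calls, NaN for
missing. The marker map carries chromosome, genetic position (cM) and an
optional physical position (bp, 1-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]

MAP_COLUMNS = ("marker", "chrom", "cM", "bp")


@dataclass
class GenotypeMatrix:
    """n lines x p markers dosage matrix with marker map metadata.

    Parameters
    ----------
    dosages
        Array of shape ``(n_lines, n_markers)`` with values in {0, 1, 2}
        or NaN for missing calls. Imputation (see :func:`qgpanel.geno.qc_filter`)
        may later introduce fractional dosages.
    line_ids, marker_ids
        Unique identifiers for rows and columns.
    marker_map
        Optional frame with columns ``marker, chrom, cM, bp`` (``bp`` may be
        absent). Markers missing from the map are treated as unmapped.
    """

    dosages: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]
    marker_map: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        n, p = self.dosages.shape
        if len(self.line_ids) != n or len(self.marker_ids) != p:
            raise ValueError(
                f"dimension mismatch: dosages {self.dosages.shape}, "
                f"{len(self.line_ids)} line ids, {len(self.marker_ids)} marker ids"
            )
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != p:
            raise ValueError("duplicate marker ids")
        if self.marker_map is not None:
            mm = self.marker_map.copy()
            if "marker" in mm.columns:
                mm = mm.set_index("marker")
            mm.index = mm.index.astype(str)
            self.marker_map = mm

    # ------------------------------------------------------------------ basics
    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(),
            list(self.line_ids),
            list(self.marker_ids),
            None if self.marker_map is None else self.marker_map.copy(),
            dict(self.meta),
        )

    # --------------------------------------------------------------- selection
    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        idx = [self.marker_ids.index(m) for m in marker_ids]
        mm = None
        if self.marker_map is not None:
            keep = [m for m in marker_ids if m in self.marker_map.index]
            mm = self.marker_map.loc[keep].copy()
        return GenotypeMatrix(
            self.dosages[:, idx], list(self.line_ids), list(marker_ids), mm, dict(self.meta)
        )

    def subset_lines(self, line_ids) -> "GenotypeMatrix":
        idx = [self.line_ids.index(l) for l in line_ids]
        mm = None if self.marker_map is None else self.marker_map.copy()
        return GenotypeMatrix(
            self.dosages[idx, :], list(line_ids), list(self.marker_ids), mm, dict(self.meta)
        )

    # ------------------------------------------------------------- frequencies
    def allele_freqs(self) -> np.ndarray:
        """Per-marker frequency of the counted allele, from observed calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_freqs(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def monomorphic_markers(self) -> list[str]:
        """Markers with no observed allelic variation (flagged, not dropped)."""
        maf = self.minor_allele_freqs()
        mono = np.isnan(maf) | (maf <= 0)
        return [m for m, flag in zip(self.marker_ids, mono) if flag]

    # ------------------------------------------------------------------- views
    def mapped_marker_ids(self) -> list[str]:
        if self.marker_map is None:
            return []
        mapped = set(self.marker_map.index[self.marker_map["cM"].notna()])
        return [m for m in self.marker_ids if m in mapped]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids)
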