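"""Shared tabular containers.

The canonical exchange formats are plain :class:`pandas.DataFrame` objects;
:class:`CommunityMatrix` bundles the sample x taxon abundance block with the
per-sample metadata (site, month) that several operations group by.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Columns that belong to sample metadata rather than to taxa.
META_COLUMNS = ("site", "month")


@dataclass
class CommunityMatrix:
    """Sample x taxon abundance matrix with site/month metadata.

    Parameters
    ----------
    abundance
        DataFrame indexed by ``sample_id`` with one column per taxon and
        nonnegative abundances (individuals per litre).
    meta
        DataFrame indexed by ``sample_id`` with columns ``site`` and
        ``month`` (integer 1-12).
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.meta is None:
            self.meta = pd.DataFrame(
                {"site": "S1", "month": 1}, index=self.abundance.index
            )
        if not self.abundance.index.is_unique:
            raise ValidationError("duplicate sample_id in abundance matrix")
        if not self.abundance.columns.is_unique:
            raise ValidationError("duplicate taxon column in abundance matrix")
        if not self.abundance.index.equals(self.meta.index):
            raise ValidationError("abundance and metadata sample indices differ")
        values = self.abundance.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("abundances must be finite")
        if (values < 0).any():
            raise ValidationError("abundances must be nonnegative")

    @property
    def samples(self) -> pd.Index:
        return self.abundance.index

    @property
    def taxa(self) -> pd.Index:
        return self.abundance.columns

    def to_frame(self) -> pd.DataFrame:
        """Wide canonical layout: sample_id, site, month, then taxon columns."""
        out = pd.concat([self.meta[list(META_COLUMNS)], self.abundance], axis=1)
        out.index.name = "sample_id"
        return out.reset_index()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CommunityMatrix":
        frame = frame.set_index("sample_id")
        meta = frame[list(META_COLUMNS)].copy()
        meta["month"] = meta["month"].astype(int)
        abundance = frame.drop(columns=list(META_COLUMNS)).astype(float)
        return cls(abundance=abundance, meta=meta)


def as_abundance(community) -> pd.DataFrame:
    """Accept either a CommunityMatrix or a bare sample x taxon DataFrame."""
    if isinstance(community, CommunityMatrix):
        return community.abundance
    return community
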