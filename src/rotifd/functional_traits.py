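"""Trait vocabulary, functional-group mapping, composition and dominance.

Four categorical trait categories describe each taxon: trophi (jaw
apparatus, 7 modalities), body-size class (3), feeding habit (4) and
swimming mode (3).  Community composition can be aggregated by any trait
category, and dominant units (taxa or modalities) are screened with an
occurrence-weighted dominance index ``Y = (n_i / N) * f_i``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import CommunityMatrix, as_abundance
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

TRAIT_CATEGORIES = ("trophi", "size", "feeding", "swimming")

#: Default modality vocabulary: 7 trophi, 3 size, 4 feeding, 3 swimming.
DEFAULT_VOCABULARY: dict[str, tuple[str, ...]] = {
    "trophi": (
        "malleate",
        "asymmetrical virgate",
        "virgate",
        "incudate",
        "ramate",
        "malleoramate",
        "forcipate",
    ),
    "size": ("<150 um", "150-300 um", ">300 um"),
    "feeding": ("filter-feeding", "predacious", "sucking", "carnivorous"),
    "swimming": ("planktonic", "benthic", "facultative planktonic"),
}

#: Dominance threshold on Y.
DEFAULT_DOMINANCE_THRESHOLD = 0.02

#: Threshold on within-group relative abundance reported as a separate flag.
DEFAULT_RELATIVE_ABUNDANCE_THRESHOLD = 0.20


def size_class(length_um: float) -> str:
    """Assign a body length (micrometres) to a size modality.

    Values exactly on a boundary (150 or 300) go to the middle class.
    """
    if length_um < 150:
        return "<150 um"
    if length_um <= 300:
        return "150-300 um"
    return ">300 um"


def _canonical_label(category: str, label: str) -> str:
    s = str(label).strip().lower()
    s = s.replace("μ", "u").replace("µ", "u")  # mu -> u
    s = s.replace("–", "-").replace("—", "-")  # dashes
    s = " ".join(s.split())
    if category == "trophi" and s.endswith(" trophi"):
        s = s[: -len(" trophi")]
    if category == "size":
        s = s.replace("um", " um").replace("  ", " ")
        s = s.replace("< 150", "<150").replace("> 300", ">300")
        s = " ".join(s.split())
    return s


def validate_trait_table(
    table: pd.DataFrame,
    vocabulary: Mapping[str, Sequence[str]] = DEFAULT_VOCABULARY,
) -> pd.DataFrame:
    """Canonicalize modality labels and reject rows outside the vocabulary.

    Returns a copy indexed by taxon with one column per trait category and
    canonical labels.  Unknown modalities raise :class:`ValidationError`
    listing every offending (taxon, category, label) triple.
    """
    for cat, mods in vocabulary.items():
        if len(mods) == 0:
            raise ConfigurationError(f"trait category {cat!r} has no modalities")
    frame = table.set_index("taxon") if "taxon" in table.columns else table.copy()
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate taxa in trait table: {dupes}")
    if len(frame) == 0:
        warnings.warn("empty trait table", stacklevel=2)
        return pd.DataFrame(columns=list(vocabulary), index=pd.Index([], name="taxon"))

    missing_cols = [c for c in vocabulary if c not in frame.columns]
    if missing_cols:
        raise ValidationError(f"trait table lacks categories: {missing_cols}")

    canonical = {
        cat: {_canonical_label(cat, m): m for m in mods}
        for cat, mods in vocabulary.items()
    }
    out = pd.DataFrame(index=frame.index)
    bad: list[tuple[str, str, str]] = []
    for cat in vocabulary:
        mapped = []
        for taxon, raw in frame[cat].items():
            key = _canonical_label(cat, raw)
            if key in canonical[cat]:
                mapped.append(canonical[cat][key])
            else:
                bad.append((str(taxon), cat, str(raw)))
                mapped.append(None)
        out[cat] = mapped
    if bad:
        raise ValidationError(f"unknown trait modalities: {bad}")
    out.index.name = "taxon"
    return out


@dataclass
class FunctionalComposition:
    """Per-sample abundance aggregated over the modalities of one category.

    Attributes
    ----------
    category
        Trait category aggregated over.
    absolute
        sample x modality absolute abundances (ind/L).
    relative
        sample x modality fractions (NaN rows where the sample total is 0).
    totals
        Per-sample total abundance.
    zero_samples
        sample_ids whose total abundance is zero (relative undefined).
    """

    category: str
    absolute: pd.DataFrame
    relative: pd.DataFrame
    totals: pd.Series
    zero_samples: list

    def to_long(self) -> pd.DataFrame:
        """Long layout: sample_id, category, modality, abundance, fraction."""
        rows = self.absolute.stack().rename("abundance").reset_index()
        rows.columns = ["sample_id", "modality", "abundance"]
        rows["fraction"] = self.relative.stack(future_stack=True).to_numpy()
        rows.insert(1, "category", self.category)
        return rows


def composition_by_modality(
    community: CommunityMatrix | pd.DataFrame,
    traits: pd.DataFrame,
    category: str,
    vocabulary: Mapping[str, Sequence[str]] = DEFAULT_VOCABULARY,
) -> FunctionalComposition:
    """Aggregate the community matrix over the modalities of one category."""
    if category not in vocabulary:
        raise ConfigurationError(f"unknown trait category {category!r}")
    abundance = as_abundance(community)
    traits = traits.set_index("taxon") if "taxon" in traits.columns else traits
    missing = [t for t in abundance.columns if t not in traits.index]
    if missing:
        raise ValidationError(f"taxa missing from trait table: {missing}")

    modality = traits.loc[abundance.columns, category]
    absolute = abundance.T.groupby(modality.to_numpy()).sum().T
    absolute = absolute.reindex(columns=list(vocabulary[category]), fill_value=0.0)
    totals = absolute.sum(axis=1)
    zero = list(totals.index[totals == 0])
    if zero:
        logger.warning("samples with zero total abundance flagged: %s", zero[:10])
    with np.errstate(invalid="ignore", divide="ignore"):
        relative = absolute.div(totals.where(totals > 0), axis=0)
    return FunctionalComposition(
        category=category,
        absolute=absolute,
        relative=relative,
        totals=totals.rename("total"),
        zero_samples=zero,
    )


def dominance_screen(
    community: CommunityMatrix,
    *,
    unit: str = "taxon",
    traits: pd.DataFrame | None = None,
    category: str | None = None,
    threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
    relative_abundance_threshold: float = DEFAULT_RELATIVE_ABUNDANCE_THRESHOLD,
) -> pd.DataFrame:
    """Screen dominant units per month group.

    For each month and each unit (taxon, or trait modality when
    ``unit="modality"``), the dominance index is ``Y = (n_i / N) * f_i``
    where ``n_i / N`` is the unit's share of the group-wide abundance and
    ``f_i`` the fraction of the group's samples in which it occurs.  A unit
    is flagged dominant when ``Y >= threshold``; a separate column flags
    whether its group-wide relative abundance exceeds
    ``relative_abundance_threshold``.
    """
    if unit == "modality":
        if traits is None or category is None:
            raise ConfigurationError("modality screening needs traits and category")
        comp = composition_by_modality(community, traits, category)
        matrix = comp.absolute
    elif unit == "taxon":
        matrix = community.abundance
    else:
        raise ConfigurationError(f"unknown dominance unit {unit!r}")

    months = community.meta["month"]
    records = []
    for month, block in matrix.groupby(months):
        if len(block) == 0:
            logger.warning("empty month group %s skipped", month)
            continue
        group_total = block.to_numpy().sum()
        if group_total == 0:
            logger.warning("month group %s has zero abundance; skipped", month)
            continue
        rel = block.sum(axis=0) / group_total
        freq = (block > 0).mean(axis=0)
        y = rel * freq
        for name in matrix.columns:
            records.append(
                {
                    "month": month,
                    "unit": name,
                    "Y": float(y[name]),
                    "relative_abundance": float(rel[name]),
                    "occurrence_frequency": float(freq[name]),
                    "dominant": bool(y[name] >= threshold),
                    "exceeds_relative_abundance": bool(
                        rel[name] > relative_abundance_threshold
                    ),
                }
            )
    return pd.DataFrame.from_records(records)
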