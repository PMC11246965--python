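"""Binary climatic suitability and relative suitability from SDM probabilities.

Probabilities of occurrence from ensemble species distribution models are
turned into presence/absence with species-specific mean cut-off values: a
species whose probability at a plot falls below its cut-off is treated as
climatically unsuitable there (equality with the cut-off counts as
suitable).  Relative suitability — probability divided by cut-off — is
the ranking key for replacement decisions: values at or above 1 mean
suitable, and larger means a better climatic match.

The two white oaks are modelled separately (codes ``qpe``/``qro``) but the
inventory only knows merged *Quercus* spp.; :func:`resolve_oaks` keeps the
more suitable of the two and judges it against the merged-oak cut-off.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from forest_adapt.registry import SpeciesRegistry

__all__ = [
    "PERIODS",
    "FUTURE_PERIODS",
    "OAK_SPLIT_CODES",
    "binarize",
    "relative_suitability",
    "resolve_oaks",
    "build_suitability_table",
    "failing_species",
]

#: Recognized climate periods (extensible: any label is accepted by the
#: table builder, these are the canonical three).
PERIODS = ("historical_1961_1990", "rcp45_2081_2100", "rcp85_2081_2100")
FUTURE_PERIODS = ("rcp45_2081_2100", "rcp85_2081_2100")

#: Pre-merge oak codes accepted in raw probability tables.
OAK_SPLIT_CODES = ("qpe", "qro")  # Quercus petraea, Quercus robur
OAK_MERGED_CODE = "que"


def binarize(probability: float, cutoff: float) -> bool:
    """True iff the occurrence probability reaches the species cut-off.

    Both arguments are percentages; equality counts as suitable (only
    strictly-below-threshold sites are assigned to zero).
    """
    if not (0 <= probability <= 100):
        raise ValueError(f"probability out of range [0, 100]: {probability}")
    if not (0 < cutoff <= 100):
        raise ValueError(f"cutoff out of range (0, 100]: {cutoff}")
    return probability >= cutoff


def relative_suitability(probability: float, cutoff: float, mode: str = "ratio") -> float:
    """Suitability relative to the species cut-off.

    ``ratio`` mode (default) returns probability/cutoff, so 1.0 marks the
    threshold exactly; ``difference`` mode returns (probability - cutoff)/100
    shifted to keep the same suitable-iff->=1 convention, i.e.
    ``1 + (probability - cutoff) / 100``.
    """
    if not (0 <= probability <= 100):
        raise ValueError(f"probability out of range [0, 100]: {probability}")
    if not (0 < cutoff <= 100):
        raise ValueError(f"cutoff out of range (0, 100]: {cutoff}")
    if mode == "ratio":
        return probability / cutoff
    if mode == "difference":
        return 1.0 + (probability - cutoff) / 100.0
    raise ValueError(f"unknown relative-suitability mode: {mode!r}")


def resolve_oaks(p_petraea: float | None, p_robur: float | None) -> tuple[float, str]:
    """Merge the two white-oak probabilities into one *Quercus* spp. value.

    The species with the higher probability wins; its probability is then
    judged against the merged-oak cut-off by the caller.  Missing values
    count as 0.  Returns ``(probability, source_code)``; ties go to
    *Q. petraea* (deterministic, codes sorted).
    """
    pp = 0.0 if p_petraea is None or (isinstance(p_petraea, float) and np.isnan(p_petraea)) else float(p_petraea)
    pr = 0.0 if p_robur is None or (isinstance(p_robur, float) and np.isnan(p_robur)) else float(p_robur)
    if pp >= pr:
        return pp, "qpe"
    return pr, "qro"


def build_suitability_table(
    raw: pd.DataFrame,
    registry: SpeciesRegistry,
    rel_mode: str = "ratio",
) -> pd.DataFrame:
    """Annotate a long-format probability table with suitability columns.

    ``raw`` needs columns ``plot_id, species, period, probability``
    (probability in percent).  Rows for the split oak codes ``qpe``/``qro``
    are merged into a single ``que`` row per plot and period, keeping the
    winner in an ``oak_source`` column.  Missing probabilities (NaN, e.g.
    plots outside a raster) are treated as 0, i.e. unsuitable.

    Returns a frame with columns
    ``plot_id, species, period, probability, suitable, relative, oak_source``.
    """
    required = {"plot_id", "species", "period", "probability"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"probability table missing columns: {sorted(missing)}")

    df = raw.loc[:, ["plot_id", "species", "period", "probability"]].copy()
    df["probability"] = df["probability"].fillna(0.0).astype(float)

    known = set(registry.codes) | set(OAK_SPLIT_CODES)
    unknown = sorted(set(df["species"]) - known)
    if unknown:
        raise ValueError(f"unknown species in probability table: {unknown}")

    is_oak = df["species"].isin(OAK_SPLIT_CODES)
    plain = df.loc[~is_oak].copy()
    plain["oak_source"] = ""

    if is_oak.any():
        oaks = df.loc[is_oak]
        merged_rows = []
        for (plot_id, period), grp in oaks.groupby(["plot_id", "period"], sort=False):
            probs = dict(zip(grp["species"], grp["probability"]))
            prob, source = resolve_oaks(probs.get("qpe"), probs.get("qro"))
            merged_rows.append(
                {
                    "plot_id": plot_id,
                    "species": OAK_MERGED_CODE,
                    "period": period,
                    "probability": prob,
                    "oak_source": source,
                }
            )
        merged = pd.DataFrame(merged_rows)
        # a pre-merged 'que' row would duplicate the synthesized one
        clash = plain.merge(merged[["plot_id", "period"]], on=["plot_id", "period"]).query("species == @OAK_MERGED_CODE")
        if not clash.empty:
            raise ValueError("probability table mixes split oak codes with merged 'que' rows for the same plot/period")
        df = pd.concat([plain, merged], ignore_index=True)
    else:
        df = plain

    cutoffs = df["species"].map({c: registry.cutoff(c) for c in registry.codes})
    out_of_range = df.loc[(df["probability"] < 0) | (df["probability"] > 100)]
    if not out_of_range.empty:
        bad = out_of_range.iloc[0]
        raise ValueError(f"probability out of range for plot {bad['plot_id']}, species {bad['species']}: {bad['probability']}")
    df["suitable"] = df["probability"].to_numpy() >= cutoffs.to_numpy()
    if rel_mode == "ratio":
        df["relative"] = df["probability"].to_numpy() / cutoffs.to_numpy()
    elif rel_mode == "difference":
        df["relative"] = 1.0 + (df["probability"].to_numpy() - cutoffs.to_numpy()) / 100.0
    else:
        raise ValueError(f"unknown relative-suitability mode: {rel_mode!r}")
    return df.reset_index(drop=True)


def failing_species(
    shares: Mapping[str, float],
    table: pd.DataFrame | Mapping[str, bool],
    period: str | None = None,
) -> set[str]:
    """Species present today that are climatically unsuitable in ``period``.

    These are considered unable to regenerate and locally extinct in the
    long term.  ``table`` is either a suitability frame (from
    :func:`build_suitability_table`, filtered by ``period`` if given) or a
    plain mapping species -> suitable flag.  Every species with share > 0
    must have a record.
    """
    occurring = {s for s, share in shares.items() if share > 0}
    if isinstance(table, pd.DataFrame):
        sub = table if period is None else table.loc[table["period"] == period]
        flags = dict(zip(sub["species"], sub["suitable"]))
    else:
        flags = dict(table)
    missing = occurring - set(flags)
    if missing:
        raise ValueError(f"no suitability record for occurring species: {sorted(missing)}")
    return {s for s in occurring if not flags[s]}
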