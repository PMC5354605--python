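"""Genetic-interaction scoring from query vs control colony arrays.

The scoring scheme mirrors the classical colony-size-ratio SGA analysis:

1. every plate is normalized to its own median colony size (absorbing
   between-plate growth differences),
2. per position, the normalized query size is divided by the normalized
   control size, giving a dimensionless fitness ratio per gene,
3. ratios from the independent query isolates are averaged,
4. mean ratios below 0.8 call a negative interaction, above 1.2 a positive
   one (strict inequalities; anything else is no interaction),
5. only calls made with the same sign in every biological replicate are
   kept as robust interactions.

All tabular results are pandas DataFrames keyed by gene id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colony_quant import PlateGrid

__all__ = [
    "normalize_plate",
    "compute_ratios",
    "mean_over_isolates",
    "classify_interactions",
    "intersect_replicates",
    "hub_fraction",
    "score_replicate",
    "score_screen",
    "recovery_metrics",
]

CALLS = ("negative", "none", "positive")


def load_gene_list(path) -> list[str]:
    """Read a one-gene-per-line text file; '#' lines are comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


@dataclass
class NormalizedPlate:
    """A plate scaled to unit median: values = size / median(retained sizes).

    Flagged or zero positions are NaN (missing) and excluded from the
    median.  With an even retained count the median is the midpoint of the
    two central order statistics.
    """

    values: np.ndarray  # rows x cols, NaN = missing
    median_size: float
    source: PlateGrid

    @property
    def genes(self) -> np.ndarray | None:
        return self.source.genes


def normalize_plate(plate: PlateGrid) -> NormalizedPlate:
    """Divide every retained colony size by the plate median.

    Raises ``ValueError`` if no position is retained (all flagged or zero).
    """
    retained = plate.retained()
    if not retained.any():
        raise ValueError(f"plate {plate.plate_id}: no retained positions to normalize")
    med = float(np.median(plate.sizes[retained]))
    values = np.where(retained, plate.sizes / med, np.nan)
    return NormalizedPlate(values=values, median_size=med, source=plate)


def compute_ratios(
    query: NormalizedPlate,
    control: NormalizedPlate,
    layout: np.ndarray | None = None,
    control_floor: float = 0.05,
) -> pd.DataFrame:
    """Per-gene query/control ratio of normalized sizes.

    ``layout`` maps grid positions to gene ids; defaults to the plates' own
    gene layout (which must agree between query and control).  The ratio is
    missing — with a recorded reason — when either side is missing or the
    normalized control falls below ``control_floor`` (a dead control pin
    cannot witness a fitness ratio).

    Returns columns: gene, ratio, reason ('' when defined).
    """
    if query.values.shape != control.values.shape:
        raise ValueError("query and control plates have different shapes")
    if layout is None:
        if query.genes is None or control.genes is None:
            raise ValueError("no gene layout available")
        if not np.array_equal(query.genes, control.genes):
            raise ValueError("query and control gene layouts disagree")
        layout = query.genes
    layout = np.asarray(layout, dtype=object)
    if layout.shape != query.values.shape:
        raise ValueError("layout shape does not match plate shape")

    has_gene = layout != ""
    q = query.values[has_gene]
    c = control.values[has_gene]
    ratio = np.full(q.shape, np.nan)
    reason = np.full(q.shape, "", dtype=object)
    q_missing = np.isnan(q)
    c_missing = np.isnan(c)
    low_control = (~c_missing) & (c < control_floor)
    ok = ~(q_missing | c_missing | low_control)
    ratio[ok] = q[ok] / c[ok]
    reason[q_missing] = "query_missing"
    reason[c_missing & ~q_missing] = "control_missing"
    reason[low_control & ~q_missing] = "control_below_floor"
    return pd.DataFrame({"gene": layout[has_gene], "ratio": ratio, "reason": reason})


def mean_over_isolates(
    isolate_ratios: list[pd.DataFrame], min_isolates: int = 2
) -> pd.DataFrame:
    """Average each gene's defined ratios over query isolates.

    Genes with fewer than ``min_isolates`` defined ratios are dropped with
    reason ``"no_ratio"`` (kept in the output with dropped=True so the loss
    is auditable).

    Returns columns: gene, mean_ratio, n_isolates_used, dropped, reason.
    """
    if not isolate_ratios:
        raise ValueError("need at least one isolate ratio table")
    merged = pd.concat(
        [df.assign(isolate=i + 1) for i, df in enumerate(isolate_ratios)],
        ignore_index=True,
    )
    grp = merged.groupby("gene", sort=True)["ratio"]
    out = grp.agg(mean_ratio="mean", n_isolates_used="count").reset_index()
    out["n_isolates_used"] = out["n_isolates_used"].astype(int)
    out["dropped"] = out["n_isolates_used"] < min_isolates
    out["reason"] = np.where(out["dropped"], "no_ratio", "")
    out.loc[out["dropped"], "mean_ratio"] = np.nan
    return out


def classify_interactions(
    scores: pd.DataFrame, low: float = 0.8, high: float = 1.2
) -> pd.DataFrame:
    """Call interactions from mean ratios by strict thresholds.

    mean_ratio < low -> negative; mean_ratio > high -> positive; otherwise
    (including exactly at a threshold, or missing) -> none.
    """
    if not (0 < low < high):
        raise ValueError("thresholds must satisfy 0 < low < high")
    out = scores.copy()
    ratio = out["mean_ratio"]
    call = np.full(len(out), "none", dtype=object)
    call[(ratio < low).to_numpy(dtype=bool)] = "negative"
    call[(ratio > high).to_numpy(dtype=bool)] = "positive"
    out["call"] = call
    return out


def intersect_replicates(replicate_calls: list[pd.DataFrame]) -> pd.DataFrame:
    """Keep interactions called with the same sign in every replicate.

    Input tables need columns gene and call.  The output has one row per
    gene seen in any replicate, with per-replicate provenance columns
    (call_rep1, call_rep2, ...), the consensus ``call`` ("none" unless the
    same non-none call was made everywhere), a ``robust`` flag, and a
    ``discordant`` flag marking genes called with opposite signs.  The
    robust interaction set is the ``robust`` subset; by construction it is
    contained in every replicate's call set.
    """
    if len(replicate_calls) < 2:
        raise ValueError("replicate intersection needs at least two replicates")
    merged = None
    for i, df in enumerate(replicate_calls, start=1):
        sub = df[["gene", "call"]].rename(columns={"call": f"call_rep{i}"})
        merged = sub if merged is None else merged.merge(sub, on="gene", how="outer")
    call_cols = [c for c in merged.columns if c.startswith("call_rep")]
    calls = merged[call_cols].fillna("none")
    consistent = calls.nunique(axis=1) == 1
    non_none = (calls != "none").all(axis=1)
    keep = (consistent & non_none).to_numpy()
    sign_map = {"negative": -1, "none": 0, "positive": 1}
    signs = calls.apply(lambda c: c.map(sign_map)).astype(int)
    discordant = ((signs.min(axis=1) < 0) & (signs.max(axis=1) > 0)).to_numpy()
    out = merged.copy()
    out["call"] = np.where(keep, calls.iloc[:, 0], "none")
    out["robust"] = keep
    out["discordant"] = discordant
    return out.sort_values("gene", ignore_index=True)


def hub_fraction(
    negatives: pd.DataFrame | list[str], hub_genes: list[str] | set[str]
) -> tuple[int, float]:
    """Fraction of negative interactors mapping to a hub gene set.

    Returns (count in hub, percent of all negatives), the percent truncated
    to one decimal place as conventionally printed.

    Raises ``ValueError`` on an empty negative set.
    """
    if isinstance(negatives, pd.DataFrame):
        neg = set(negatives.loc[negatives["call"] == "negative", "gene"])
    else:
        neg = set(negatives)
    if not neg:
        raise ValueError("empty negative-interaction set")
    n_in_hub = len(neg & set(hub_genes))
    percent = math.floor(1000.0 * n_in_hub / len(neg)) / 10.0
    return n_in_hub, percent


# --------------------------------------------------------------------------
# whole-screen drivers
# --------------------------------------------------------------------------


def score_replicate(
    plates: list[PlateGrid],
    low: float = 0.8,
    high: float = 1.2,
    min_isolates: int = 2,
    control_floor: float = 0.05,
) -> pd.DataFrame:
    """Score one biological replicate from its query and control plates.

    Plates are paired by (isolate, plate_id page); each pair is normalized
    separately, ratios per isolate are pooled across plate pages, averaged
    over isolates and classified.
    """
    queries = [p for p in plates if p.array_role == "query"]
    controls = {(p.isolate, p.plate_id.rsplit("_", 1)[-1]): p
                for p in plates if p.array_role == "control"}
    per_isolate: dict[int, list[pd.DataFrame]] = {}
    for q in queries:
        key = (q.isolate, q.plate_id.rsplit("_", 1)[-1])
        if key not in controls:
            raise ValueError(f"no control plate matching query {q.plate_id}")
        ratios = compute_ratios(
            normalize_plate(q), normalize_plate(controls[key]),
            control_floor=control_floor,
        )
        per_isolate.setdefault(q.isolate, []).append(ratios)
    isolate_tables = [
        pd.concat(tabs, ignore_index=True) for _, tabs in sorted(per_isolate.items())
    ]
    means = mean_over_isolates(isolate_tables, min_isolates=min_isolates)
    return classify_interactions(means, low=low, high=high)


def score_screen(
    screen_plates: list[PlateGrid],
    low: float = 0.8,
    high: float = 1.2,
    min_isolates: int = 2,
    control_floor: float = 0.05,
) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Score a full screen: per-replicate calls intersected across replicates.

    Returns (robust interaction table, per-replicate call tables).
    """
    reps = sorted({p.replicate for p in screen_plates})
    rep_tables = [
        score_replicate(
            [p for p in screen_plates if p.replicate == r],
            low=low, high=high, min_isolates=min_isolates,
            control_floor=control_floor,
        )
        for r in reps
    ]
    robust = intersect_replicates(rep_tables)
    return robust, rep_tables


def recovery_metrics(robust: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Recall and precision of robust calls against a planted truth table.

    One row per interaction sign with columns: call, n_true, n_called,
    n_correct, recall, precision.
    """
    called = robust.set_index("gene")["call"] if len(robust) else pd.Series(dtype=object)
    rows = []
    for sign in ("negative", "positive"):
        true_set = set(truth.loc[truth["category"] == sign, "gene"])
        called_set = set(called[called == sign].index)
        tp = len(true_set & called_set)
        rows.append(
            {
                "call": sign,
                "n_true": len(true_set),
                "n_called": len(called_set),
                "n_correct": tp,
                "recall": tp / len(true_set) if true_set else np.nan,
                "precision": tp / len(called_set) if called_set else np.nan,
            }
        )
    return pd.DataFrame(rows)
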