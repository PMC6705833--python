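"""Wikimedia clickstream parsing, aggregation and categorization.

Monthly clickstream dumps are tab-separated ``(prev, curr, type, n)``
records: how many times, during the month, a reader arrived at page
``curr`` from referrer ``prev``. Referrers are either real page titles
or reserved aggregate tokens (``other-search`` for search engines,
``other-empty`` for refererless HTTPS traffic, and so on). This module
filters the dumps to a set of target pages, merges months by exact
key-wise summation, rolls inbound referrers up into human-curated
categories, and exports a Sankey-style flow document whose inbound side
conserves the raw counts exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections.abc import Iterable, Mapping
from pathlib import Path

import pandas as pd

from .errors import ConservationError, InputFormatError, ParameterError

__all__ = [
    "RESERVED_CATEGORIES",
    "read_clickstream",
    "merge_months",
    "read_category_map",
    "categorize",
    "topk_outbound",
    "sankey_export",
    "write_sankey",
    "normalize_title",
]

logger = logging.getLogger(__name__)

#: Display categories for the dumps' reserved aggregate referrer tokens.
RESERVED_CATEGORIES: Mapping[str, str] = {
    "other-search": "Search engines",
    "other-external": "Other external",
    "other-empty": "Unknown/refererless",
    "other-internal": "Other Wikimedia",
    "other-other": "Other",
}

_COLUMNS = ["prev", "curr", "type", "n"]


def normalize_title(title: str) -> str:
    """Normalize a page title for matching: spaces become underscores.

    Matching stays case-sensitive otherwise — dumps use underscores,
    hand-curated category maps often use spaces.
    """
    return str(title).strip().replace(" ", "_")


def read_clickstream(path, target_pages: Iterable[str]) -> pd.DataFrame:
    """Read a clickstream TSV, keeping edges touching the target pages.

    Rows whose ``curr`` is a target are inbound; rows whose ``prev`` is a
    target are outbound (``direction`` column). Malformed rows (too few
    fields, non-integer or non-positive counts) are skipped and counted,
    with the terminal tally logged.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"clickstream file not found: {path}")
    targets = {normalize_title(t) for t in target_pages}
    if not targets:
        raise ParameterError("at least one target page is required")

    rows = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and [f.strip().lower() for f in fields[:4]] == _COLUMNS:
                continue  # optional header line
            if len(fields) < 4:
                skipped += 1
                logger.warning("%s:%d: skipped row with %d fields", path, lineno, len(fields))
                continue
            prev, curr, type_, n_raw = (f.strip() for f in fields[:4])
            try:
                n = int(n_raw)
            except ValueError:
                skipped += 1
                logger.warning("%s:%d: skipped row with non-integer count %r", path, lineno, n_raw)
                continue
            if n < 1:
                skipped += 1
                logger.warning("%s:%d: skipped row with non-positive count %d", path, lineno, n)
                continue
            prev_n, curr_n = normalize_title(prev), normalize_title(curr)
            if curr_n in targets:
                rows.append((prev_n, curr_n, type_, n, "in"))
            elif prev_n in targets:
                rows.append((prev_n, curr_n, type_, n, "out"))
    if skipped:
        logger.warning("%s: skipped %d malformed rows in total", path, skipped)

    edges = pd.DataFrame(rows, columns=_COLUMNS + ["direction"])
    if len(edges) == 0:
        warnings.warn(f"{path}: no edges matched the target pages", stacklevel=2)
    return edges


def merge_months(edge_sets: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Sum counts over identical (prev, curr, type) keys across months."""
    frames = [f for f in edge_sets]
    if not frames:
        raise ParameterError("at least one edge set is required")
    stacked = pd.concat(frames, ignore_index=True)
    if len(stacked) == 0:
        return stacked
    keys = ["prev", "curr", "type"]
    if "direction" in stacked.columns:
        keys.append("direction")
    merged = stacked.groupby(keys, as_index=False)["n"].sum()
    return merged.sort_values(["n", "prev", "curr"], ascending=[False, True, True]).reset_index(
        drop=True
    )


def read_category_map(path) -> dict[str, str]:
    """Read a (title, category) CSV into a normalized-title mapping."""
    df = pd.read_csv(path, dtype=str)
    lower = {c.lower(): c for c in df.columns}
    title_col = lower.get("title") or lower.get("page") or df.columns[0]
    cat_col = lower.get("category") or df.columns[-1]
    return {
        normalize_title(row[title_col]): str(row[cat_col]).strip()
        for _, row in df.iterrows()
    }


def categorize(
    edges: pd.DataFrame,
    category_map: Mapping[str, str],
    fallback: str = "Uncategorized",
) -> tuple[pd.Series, list[str]]:
    """Roll inbound referrer counts up into categories.

    Reserved aggregate tokens get their fixed display categories; every
    other referrer is looked up (after title normalization) in
    ``category_map``, with unmapped titles assigned ``fallback`` and
    returned for review. The category totals sum to the raw inbound
    count total exactly.
    """
    inbound = edges[edges["direction"] == "in"] if "direction" in edges.columns else edges
    mapping = {normalize_title(k): v for k, v in category_map.items()}

    unmapped: set[str] = set()

    def label(prev: str) -> str:
        if prev in RESERVED_CATEGORIES:
            return RESERVED_CATEGORIES[prev]
        if prev in mapping:
            return mapping[prev]
        unmapped.add(prev)
        return fallback

    if len(inbound) == 0:
        return pd.Series(dtype="int64", name="n"), []
    labelled = inbound.assign(category=inbound["prev"].map(label))
    totals = labelled.groupby("category")["n"].sum().astype("int64").sort_values(ascending=False)
    if (raw := int(inbound["n"].sum())) != int(totals.sum()):
        raise ConservationError(
            f"category totals ({int(totals.sum())}) != raw inbound counts ({raw})"
        )
    return totals, sorted(unmapped)


def topk_outbound(edges: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k outbound internal-link destinations by count.

    Only ``type == "link"`` edges count as internal Wikipedia referrals.
    Ranking is by descending count with ties broken lexicographically by
    destination title; if fewer than ``k`` edges exist, all are returned.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    outbound = edges[edges["direction"] == "out"] if "direction" in edges.columns else edges
    outbound = outbound[outbound["type"] == "link"]
    if len(outbound) == 0:
        return outbound.copy()
    ranked = outbound.sort_values(["n", "curr"], ascending=[False, True], kind="stable")
    return ranked.head(k).reset_index(drop=True)


def sankey_export(
    category_totals: pd.Series,
    topk: pd.DataFrame,
    target_label: str,
) -> dict:
    """Build a Sankey flow document: categories -> target -> top-k pages.

    The document is plain JSON-serializable ``{"nodes": [...], "links":
    [...]}`` with integer link weights, compatible with common Sankey
    renderers. Inbound conservation (sum of inbound link weights equals
    the sum of the category totals) is re-checked as a bug guard.
    """
    if len(category_totals) == 0:
        raise ParameterError("inbound category totals are empty")
    if (category_totals < 1).any():
        raise ParameterError("every category total must be >= 1")

    nodes = [{"name": str(c)} for c in category_totals.index]
    target_idx = len(nodes)
    nodes.append({"name": str(target_label)})
    links = [
        {"source": i, "target": target_idx, "value": int(v)}
        for i, (_, v) in enumerate(category_totals.items())
    ]
    inbound_total = int(category_totals.sum())
    if sum(l["value"] for l in links) != inbound_total:
        raise ConservationError("inbound Sankey links do not conserve category totals")

    for _, row in topk.iterrows():
        nodes.append({"name": str(row["curr"])})
        links.append({"source": target_idx, "target": len(nodes) - 1, "value": int(row["n"])})

    return {"nodes": nodes, "links": links, "inbound_total": inbound_total}


def write_sankey(document: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(document, fh, indent=2, ensure_ascii=False)
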