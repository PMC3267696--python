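"""Raw-tag counting, QC filtering, TPM normalization and library summaries.

QC follows the filter taxonomy of the study design: a tag is *low quality*
when it contains an ambiguous base (anything outside ACGT) or is a copy of
the adaptor; the remainder are *reliable* tags.  TPM (transcripts per
million) is computed on the reliable total, and reliable tags below the
abundance floor (default 3 TPM) are then dropped from the clean table —
they still count toward the reliable total and the distinct-tag tally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_ADAPTOR,
    TAG_LEN,
    LibraryId,
    LibrarySummary,
    RawTagLibrary,
    TagCountTable,
)

DEFAULT_TPM_MIN = 3.0


def count_tags(raw: RawTagLibrary | list[str],
               library_id: LibraryId | None = None) -> TagCountTable:
    """Count distinct tags of a raw library (pre-QC; TPM left unset).

    Rejects tags of the wrong length, reporting the position of the first
    offender.  The sum of counts always equals the raw depth.
    """
    if isinstance(raw, RawTagLibrary):
        tags = raw.tags
        library_id = raw.library_id
        lengths = np.char.str_len(tags)
    else:
        tags = np.asarray(raw, dtype=object)
        lengths = np.array([len(t) for t in tags]) if len(tags) else np.array([], dtype=int)
    bad = np.nonzero(lengths != TAG_LEN)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"tag at position {i} has length {int(lengths[i])}, expected {TAG_LEN}")
    if len(tags) == 0:
        table = pd.DataFrame({"tag": pd.Series([], dtype=str),
                              "count": pd.Series([], dtype=int),
                              "tpm": pd.Series([], dtype=float)})
        return TagCountTable(library_id=library_id, table=table)
    uniq, counts = np.unique(np.asarray(tags, dtype=f"S{TAG_LEN}"), return_counts=True)
    table = pd.DataFrame({
        "tag": [t.decode() for t in uniq],
        "count": counts.astype(int),
        "tpm": np.nan,
    })
    return TagCountTable(library_id=library_id, table=table)


def _low_quality_mask(tags: pd.Series, adaptor: str, substring: bool) -> np.ndarray:
    ambiguous = ~tags.str.fullmatch("[ACGT]*").to_numpy()
    if substring:
        is_adaptor = tags.str.contains(adaptor, regex=False).to_numpy()
    else:
        is_adaptor = (tags == adaptor).to_numpy()
    return ambiguous | is_adaptor


def qc_filter(table: TagCountTable,
              adaptor: str = DEFAULT_ADAPTOR,
              tpm_min: float = DEFAULT_TPM_MIN,
              adaptor_substring: bool = False) -> tuple[TagCountTable, LibrarySummary]:
    """Apply the QC filters and normalize to TPM.

    Returns the clean table (reliable tags at >= ``tpm_min`` TPM) and the
    library summary ledger.  "Below 3 TPM" is read literally: tags at
    exactly the threshold are retained.
    """
    df = table.table
    total = int(df["count"].sum())
    lowq = _low_quality_mask(df["tag"], adaptor, adaptor_substring)
    low_quality_count = int(df.loc[lowq, "count"].sum())
    reliable = df.loc[~lowq].copy()
    reliable_total = total - low_quality_count
    distinct_count = int(len(reliable))

    if reliable_total == 0:
        clean = reliable.iloc[0:0].copy()
    else:
        reliable["tpm"] = reliable["count"] / reliable_total * 1e6
        clean = reliable.loc[reliable["tpm"] >= tpm_min].reset_index(drop=True)

    summary = LibrarySummary(
        library_id=table.library_id,
        total_sequences=total,
        low_quality_count=low_quality_count,
        reliable_count=reliable_total,
        distinct_count=distinct_count,
    )
    return TagCountTable(library_id=table.library_id, table=clean), summary


def _round_half_up(x: float, decimals: int = 0) -> float:
    f = 10.0 ** decimals
    return float(np.floor(x * f + 0.5) / f)


def summarize_libraries(summaries: list[LibrarySummary]) -> dict[str, float | int]:
    """Range report over libraries: reliable totals (millions, 1 dp) and
    distinct-tag counts (nearest thousand)."""
    if not summaries:
        raise ValueError("need at least one library summary")
    reliable = [s.reliable_count for s in summaries]
    distinct = [s.distinct_count for s in summaries]
    return {
        "reliable_min_millions": _round_half_up(min(reliable) / 1e6, 1),
        "reliable_max_millions": _round_half_up(max(reliable) / 1e6, 1),
        "distinct_min": int(_round_half_up(min(distinct) / 1000) * 1000),
        "distinct_max": int(_round_half_up(max(distinct) / 1000) * 1000),
    }


def abundance_distribution(clean: TagCountTable,
                           thresholds: list[int]) -> pd.DataFrame:
    """Distinct- and total-tag fractions per count bin.

    ``thresholds`` are ascending lower bounds; bin i covers counts in
    [thresholds[i], thresholds[i+1]) and the last bin is open-ended.
    """
    if len(clean.table) == 0:
        raise ValueError("empty tag table")
    if list(thresholds) != sorted(thresholds) or len(set(thresholds)) != len(thresholds):
        raise ValueError("thresholds must be strictly ascending")
    counts = clean.table["count"].to_numpy()
    edges = list(thresholds) + [np.inf]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (counts >= lo) & (counts < hi)
        label = f">={lo}" if np.isinf(hi) else (f"{lo}" if hi == lo + 1 else f"{lo}-{int(hi) - 1}")
        rows.append((label, sel.sum() / len(counts), counts[sel].sum() / counts.sum()))
    return pd.DataFrame(rows, columns=["bin", "distinct_fraction", "total_fraction"])


def concentration_curve(clean: TagCountTable) -> pd.DataFrame:
    """Cumulative total-tag share of the most abundant distinct tags.

    Rows are sorted by descending count; ``distinct_fraction`` is the
    cumulative share of distinct tags and ``total_fraction`` the share of
    total tag mass they carry (a Lorenz-type concentration curve).
    """
    counts = np.sort(clean.table["count"].to_numpy())[::-1]
    if counts.size == 0:
        raise ValueError("empty tag table")
    return pd.DataFrame({
        "distinct_fraction": np.arange(1, counts.size + 1) / counts.size,
        "total_fraction": np.cumsum(counts) / counts.sum(),
    })


def saturation_curve(raw: RawTagLibrary,
                     step: int,
                     seed: int = 0,
                     adaptor: str = DEFAULT_ADAPTOR,
                     reliable_only: bool = True) -> pd.DataFrame:
    """Distinct-tag counts along a without-replacement subsampling ladder.

    The tag stream is shuffled once (seeded), then distinct tags are counted
    at depths step, 2*step, ... up to the full stream (the final point is
    always included).  By default the curve is computed on the reliable
    tags — distinct-tag saturation is a statement about the transcript tag
    universe, not about noise reads, and the study counts distinct tags
    after QC.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    tags = raw.tags
    if reliable_only and len(tags):
        tags = tags[_reliable_mask_bytes(tags, adaptor)]
    n = len(tags)
    if n == 0:
        return pd.DataFrame({"depth": [], "distinct": []})
    if step > n:
        raise ValueError(f"step {step} exceeds usable depth {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    codes = pd.factorize(tags[perm])[0]
    first = np.full(codes.max() + 1, n, dtype=np.int64)
    np.minimum.at(first, codes, np.arange(n))
    first.sort()
    depths = list(range(step, n + 1, step))
    if depths[-1] != n:
        depths.append(n)
    distinct = np.searchsorted(first, depths, side="left")
    return pd.DataFrame({"depth": depths, "distinct": distinct.astype(int)})


def _reliable_mask_bytes(tags: np.ndarray, adaptor: str) -> np.ndarray:
    """Vectorised reliability mask on an S21 array."""
    mat = np.frombuffer(tags.tobytes(), dtype="u1").reshape(len(tags), TAG_LEN)
    ok = np.zeros(256, dtype=bool)
    ok[np.frombuffer(b"ACGT", dtype="u1")] = True
    good = ok[mat].all(axis=1)
    return good & (tags != adaptor.encode())
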