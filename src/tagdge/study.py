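"""Published sequencing statistics of the eight-library study design.

These are the library-level tag tallies of the original sweet-orange fruit
profiling experiment (WT 'Anliu' and its red-flesh mutant MT at 120, 150,
190 and 220 DAF) that the synthetic generator emulates.  They serve as
fixed inputs for exercising the summary arithmetic: feeding the raw totals
and low-quality counts through :class:`~tagdge.types.LibrarySummary`
reproduces the published reliable counts and 2-dp percentages.

``printed_low_quality_pct`` for MT 120 DAF is 8.99 while the counts give
9.00; the implementation follows its own arithmetic and the discrepancy is
simply recorded here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import LibraryId, LibrarySummary


@dataclass(frozen=True)
class PublishedRow:
    library_id: LibraryId
    total: int
    low_quality: int
    reliable: int
    distinct: int
    printed_low_quality_pct: float
    printed_reliable_pct: float
    printed_distinct_pct: float

    def summary(self) -> LibrarySummary:
        return LibrarySummary(
            library_id=self.library_id,
            total_sequences=self.total,
            low_quality_count=self.low_quality,
            reliable_count=self.total - self.low_quality,
            distinct_count=self.distinct,
        )


STUDY_LIBRARIES: tuple[PublishedRow, ...] = (
    PublishedRow(LibraryId("WT", 120), 2_718_771, 187_214, 2_531_557, 60_841, 6.89, 93.11, 2.24),
    PublishedRow(LibraryId("WT", 150), 4_184_144, 393_141, 3_791_003, 111_341, 9.40, 90.60, 2.66),
    PublishedRow(LibraryId("WT", 190), 4_417_154, 356_403, 4_060_751, 95_693, 8.07, 91.93, 2.17),
    PublishedRow(LibraryId("WT", 220), 4_564_850, 397_623, 4_167_227, 101_845, 8.71, 91.29, 2.23),
    PublishedRow(LibraryId("MT", 120), 3_998_867, 359_939, 3_638_928, 101_301, 8.99, 91.00, 2.53),
    PublishedRow(LibraryId("MT", 150), 3_254_246, 263_844, 2_990_402, 92_270, 8.11, 91.89, 2.84),
    PublishedRow(LibraryId("MT", 190), 4_275_571, 401_180, 3_874_391, 104_280, 9.38, 90.62, 2.44),
    PublishedRow(LibraryId("MT", 220), 4_745_537, 451_906, 4_293_631, 113_006, 9.52, 90.48, 2.38),
)

#: rows whose printed low-quality percentage disagrees with its own counts
INCONSISTENT_LOW_QUALITY_ROWS = (LibraryId("MT", 120),)
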