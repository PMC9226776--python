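"""Hit-rate arithmetic for function-based (activity plate) screening libraries.

For each metagenomic clone library the two standard yield measures are
computed from clone count, mean insert size and confirmed positive hits:

    hits_per_million_clones = hits * 1e6 / clones
    gb_screened             = clones * mean_insert_kb * 1e3 / 1e9
    hits_per_gb             = hits / gb_screened

Display rounding follows common reporting: per-million to the nearest
integer, per-Gb to one decimal, Gb totals to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["LibraryRecord", "library_hit_rates"]


@dataclass
class LibraryRecord:
    library_id: str
    sample: str
    clones: int
    mean_insert_kb: float
    confirmed_hits: int

    def __post_init__(self) -> None:
        if self.clones <= 0:
            raise ValueError(f"library {self.library_id!r}: clones must be positive")
        if self.mean_insert_kb <= 0:
            raise ValueError(f"library {self.library_id!r}: mean insert must be positive")
        if not 0 <= self.confirmed_hits <= self.clones:
            raise ValueError(f"library {self.library_id!r}: hits outside [0, clones]")


def library_hit_rates(records: Sequence[LibraryRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-library hit rates and per-sample totals.

    Returns (per_library, per_sample).  ``per_library`` columns carry the
    exact values plus display-rounded twins; per-sample totals sum screened
    gigabases and confirmed hits.
    """
    rows = []
    for rec in records:
        gb = rec.clones * rec.mean_insert_kb * 1e3 / 1e9
        per_million = rec.confirmed_hits * 1e6 / rec.clones
        per_gb = rec.confirmed_hits / gb
        rows.append(
            {
                "library_id": rec.library_id,
                "sample": rec.sample,
                "clones": rec.clones,
                "mean_insert_kb": rec.mean_insert_kb,
                "confirmed_hits": rec.confirmed_hits,
                "gb_screened": gb,
                "hits_per_million_clones": per_million,
                "hits_per_gb": per_gb,
                "hits_per_million_display": round(per_million),
                "hits_per_gb_display": round(per_gb, 1),
            }
        )
    per_library = pd.DataFrame(rows)
    per_sample = (
        per_library.groupby("sample", sort=False)
        .agg(
            gb_screened=("gb_screened", "sum"),
            confirmed_hits=("confirmed_hits", "sum"),
            clones=("clones", "sum"),
        )
        .reset_index()
    )
    per_sample["gb_screened_display"] = per_sample["gb_screened"].round(2)
    return per_library, per_sample


def read_library_tsv(path) -> list[LibraryRecord]:
    df = pd.read_csv(path, sep="\t")
    need = {"library_id", "sample", "clones", "mean_insert_kb", "confirmed_hits"}
    if not need <= set(df.columns):
        raise ValueError(f"library TSV needs columns {sorted(need)}")
    return [
        LibraryRecord(
            str(r.library_id), str(r.sample), int(r.clones),
            float(r.mean_insert_kb), int(r.confirmed_hits),
        )
        for r in df.itertuples()
    ]
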