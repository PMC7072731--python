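"""Binding-domain window extraction for motif discovery.

Ligand-binding sites annotated at single residues are expanded into
fixed-width sequence windows (21 residues by default, site at the center)
and written as FASTA for an external motif finder such as MEME, e.g.::

    meme windows.fasta -protein -nmotifs 10 -evt 0.05

Sites within half a window of a sequence terminus yield clipped fragments,
flagged ``full_width=False`` so the user can filter them.  All coordinates
in tables and headers are 1-based inclusive (UniProt convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from ubp_pred.io_formats import ProteinRecord, write_fasta

DEFAULT_WIDTH = 21
DEFAULT_MIN_WIDTH = 8


@dataclass(frozen=True)
class BindingWindow:
    """A fixed-width fragment centered on one annotated binding site."""

    protein_id: str
    site_position: int  # 1-based
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    fragment: str
    full_width: bool

    def __len__(self) -> int:
        return len(self.fragment)


def extract_windows(
    records: list[ProteinRecord],
    sites: list[tuple[str, int]],
    width: int = DEFAULT_WIDTH,
) -> list[BindingWindow]:
    """Slice a ``width``-residue window around each annotated binding site.

    ``width`` must be odd so the site sits at the exact center of an
    interior window.  Sites naming unknown proteins or positions outside
    the sequence are collected and reported together in one error.
    """
    if width % 2 == 0 or width < 1:
        raise ValueError(f"width must be a positive odd integer, got {width}")
    half = width // 2
    by_id = {r.id: r for r in records}

    bad_rows: list[str] = []
    windows: list[BindingWindow] = []
    for row_no, (pid, pos) in enumerate(sites, start=1):
        rec = by_id.get(pid)
        if rec is None:
            bad_rows.append(f"row {row_no}: unknown protein {pid!r}")
            continue
        if not 1 <= pos <= rec.length:
            bad_rows.append(
                f"row {row_no}: position {pos} outside 1..{rec.length} of {pid!r}"
            )
            continue
        start = max(1, pos - half)
        end = min(rec.length, pos + half)
        fragment = rec.sequence[start - 1 : end]
        windows.append(
            BindingWindow(
                protein_id=pid,
                site_position=pos,
                start=start,
                end=end,
                fragment=fragment,
                full_width=(end - start + 1 == width),
            )
        )
    if bad_rows:
        raise ValueError("invalid binding-site rows:\n" + "\n".join(bad_rows))
    return windows


def write_meme_input(
    windows: list[BindingWindow],
    path: str | Path,
    min_width: int = DEFAULT_MIN_WIDTH,
) -> int:
    """Write window fragments as FASTA for motif discovery; returns the count.

    Fragments shorter than ``min_width`` (clipped hard against a terminus)
    are excluded.  Headers are ``proteinid|site=P`` with P the 1-based site
    position, so each fragment stays traceable to its source annotation.
    """
    kept = [w for w in windows if len(w) >= min_width]
    records = [
        ProteinRecord(f"{w.protein_id}|site={w.site_position}", w.fragment)
        for w in kept
    ]
    write_fasta(records, path)
    return len(kept)
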