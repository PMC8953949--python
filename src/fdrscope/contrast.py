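"""Contrast-alignment rendering and PyMOL selection scripts.

A contrast alignment juxtaposes representative foreground sequences of one
hierarchy node with the background frequency of each pattern residue set,
flagging pattern columns so differential conservation is visible at a
glance.  Output is plain text plus an HTML variant; residue selections are
also emitted as PyMOL scripts.
"""

from __future__ import annotations

import html as _html

import numpy as np

from .errors import DomainError
from .msa import MSA
from .partition import Hierarchy

MARKER_PREFIX = "MARK "


def _representatives(h: Hierarchy, node_id: int, n: int, seed: int | None):
    fg = sorted(h.foreground(node_id))
    if seed is None:
        return fg[:n]
    rng = np.random.default_rng(seed)
    if len(fg) <= n:
        return fg
    return [fg[i] for i in sorted(rng.choice(len(fg), size=n, replace=False))]


def render_contrast_alignment(
    h: Hierarchy,
    msa: MSA,
    node_id: int,
    n_representatives: int = 10,
    seed: int | None = None,
) -> tuple[str, str]:
    """Plain-text and HTML contrast alignment for one non-root node.

    Pattern columns are uppercased and flagged by a ``^`` marker row; all
    other columns are lowercased.  Beneath the block, one line per pattern
    column reports the background frequency of the pattern residue set.
    Representatives are the first n foreground members by id, or a seeded
    random sample when `seed` is given.
    """
    if node_id == h.root_id:
        raise DomainError("the root has no pattern to contrast")
    node = h.nodes[node_id]
    reps = _representatives(h, node_id, n_representatives, seed)
    pattern_cols = {p.column for p in node.pattern}
    bg_ids = sorted(h.background(node_id))
    width = max([len(MARKER_PREFIX.strip())] + [len(r) for r in reps]) + 2

    marker = "".join("^" if c + 1 in pattern_cols else " " for c in range(msa.n_columns))
    lines = [
        f"# node {node_id}: {len(node.pattern)} pattern positions, "
        f"{len(h.foreground(node_id))} foreground / {len(bg_ids)} background sequences",
        f"{MARKER_PREFIX:<{width}}{marker}".rstrip(),
    ]
    rows = []
    for rid in reps:
        res = msa[rid].residues
        shown = "".join(
            ch.upper() if c + 1 in pattern_cols else ch.lower()
            for c, ch in enumerate(res)
        )
        rows.append((rid, shown))
        lines.append(f"{rid:<{width}}{shown}")

    freq_lines = []
    bg_mat = msa.to_matrix()[[msa.index_of(i) for i in bg_ids]] if bg_ids else None
    for p in sorted(node.pattern, key=lambda q: q.column):
        if bg_mat is not None and p.bg_total > 0:
            pct = 100.0 * p.bg_matches / p.bg_total
        else:
            pct = 0.0
        freq_lines.append(f"# col {p.column} {p.residue_set} bg {pct:.1f}%")
    lines.extend(freq_lines)
    text = "\n".join(lines) + "\n"

    # HTML variant: pattern columns highlighted
    cells = []
    for rid, shown in rows:
        spans = "".join(
            f'<span class="pat">{_html.escape(ch)}</span>'
            if c + 1 in pattern_cols
            else _html.escape(ch)
            for c, ch in enumerate(shown)
        )
        cells.append(f"<tr><th>{_html.escape(rid)}</th><td><code>{spans}</code></td></tr>")
    html_doc = (
        "<!DOCTYPE html><html><head><style>"
        ".pat{background:#fdd;font-weight:bold}</style></head><body>"
        f"<h3>node {node_id}</h3><table>" + "".join(cells) + "</table><ul>"
        + "".join(f"<li>{_html.escape(fl[2:])}</li>" for fl in freq_lines)
        + "</ul></body></html>"
    )
    return text, html_doc


def parse_marker_columns(text: str) -> set[int]:
    """Recover the 1-based pattern column set from a rendered marker row.

    The marker row is padded to the same offset as the sequence rows, so the
    residue start column of any sequence row locates the marker payload.
    """
    lines = text.splitlines()
    marker_line = next(
        (l for l in lines if l.startswith(MARKER_PREFIX.strip())), None
    )
    seq_line = next(
        (
            l
            for l in lines
            if l and not l.startswith("#") and not l.startswith(MARKER_PREFIX.strip())
        ),
        None,
    )
    if marker_line is None or seq_line is None:
        return set()
    offset = len(seq_line) - len(seq_line.split()[-1])
    return {i - offset + 1 for i, ch in enumerate(marker_line) if ch == "^"}


def emit_pymol_script(positions: list, chain: str, selection_name: str,
                      color: str = "red") -> str:
    """PyMOL commands selecting and showing a residue set.

    Emits a ``select`` line with residues ascending, then ``show sticks``
    and a color line; the format is byte-stable across invocations.
    """
    if not positions:
        raise DomainError("empty residue list")
    resi = "+".join(str(p) for p in sorted(positions, key=lambda v: (isinstance(v, str), v)))
    return (
        f"select {selection_name}, chain {chain} and resi {resi}\n"
        f"show sticks, {selection_name}\n"
        f"color {color}, {selection_name}\n"
    )
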