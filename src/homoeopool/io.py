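"""Plain-text input/output: FASTA, TSV tables, config files, diagrams.

All table writers prepend a comment header carrying the seed so that any
output file identifies the experiment that produced it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .contigs import Contig, MarkerOrder


def write_fasta(path, sequences: Dict[str, str],
                description: str = "") -> None:
    records = [SeqRecord(Seq(s), id=name, description=description)
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(df: pd.DataFrame, path, seed: Optional[int] = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_config(path, values: Dict) -> None:
    with Path(path).open("w") as fh:
        for key, val in values.items():
            fh.write(f"{key} = {val!r}\n")


def read_config(path) -> Dict:
    import ast
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        out[key.strip()] = ast.literal_eval(val.strip())
    return out


def read_alignment_hits(path) -> List:
    """Read 12-column tabular alignment hits (query, subject, % identity,
    alignment length, mismatches, gap opens, q.start, q.end, s.start,
    s.end, e-value, bit score; 1-based inclusive coordinates)."""
    from .discovery import Hsp
    cols = ["query_id", "subject_id", "identity_pct", "length", "mismatch",
            "gapopen", "qstart", "qend", "sstart", "send", "evalue",
            "bitscore"]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    hsps = []
    for row in df.itertuples(index=False):
        ss, se = sorted((row.sstart, row.send))
        hsps.append(Hsp(str(row.query_id), str(row.subject_id),
                        row.qstart - 1, row.qend, ss - 1, se,
                        int(row.length), float(row.identity_pct)))
    return hsps


def contig_diagram(contigs: Dict[str, List[Contig]],
                   marker_order: MarkerOrder) -> str:
    """Plain-text diagram: one row per clone, one column per marker."""
    n = len(marker_order)
    lines = ["markers: " + " ".join(marker_order.ids)]
    for sub in sorted(contigs):
        for contig in contigs[sub]:
            lo, hi = contig.span
            lines.append(f"[{contig.contig_id}] markers {lo}-{hi}, "
                         f"{len(contig.clone_markers)} clones")
            for li in contig.members:
                ms = contig.clone_markers[li]
                row = "".join("#" if m in ms else
                              ("-" if min(ms) < m < max(ms) else ".")
                              for m in range(n))
                lines.append(f"  {li:>6} {row}")
    return "\n".join(lines)


def export_contigs(contigs: Dict[str, List[Contig]],
                   marker_order: MarkerOrder) -> pd.DataFrame:
    rows = []
    for sub in sorted(contigs):
        for contig in contigs[sub]:
            for li in contig.members:
                ms = contig.clone_markers[li]
                rows.append((sub, contig.contig_id, li,
                             marker_order.ids[min(ms)],
                             marker_order.ids[max(ms)], len(ms)))
    return pd.DataFrame(rows, columns=["subgenome", "contig_id",
                                       "linear_index", "first_marker",
                                       "last_marker", "n_markers"])
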