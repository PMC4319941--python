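"""Optional adapter running external NCBI BLAST+ and parsing tabular output.

Used only when a run is configured with ``aligner: blast``; the internal
Smith-Waterman engine is the default and carries all correctness guarantees.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Mapping

from .local import LocalAlignment

_OUTFMT = "6 qseqid sseqid pident length qstart qend sstart send evalue bitscore"


def blast_available(program: str = "blastp") -> bool:
    return shutil.which(program) is not None


def _write_fasta(path: Path, records: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def blast_align_all(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    program: str = "blastp",
    evalue: float = 1e-5,
) -> list[LocalAlignment]:
    """All-vs-all hits from ``blastp``/``blastn``/``tblastn`` as LocalAlignments.

    Coverage fields are computed from the reported spans; scores are rounded
    bitscores (BLAST does not expose raw Smith-Waterman scores in outfmt 6).
    """
    if not blast_available(program):
        raise RuntimeError(f"{program} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "q.fasta"
        spath = Path(tmp) / "s.fasta"
        _write_fasta(qpath, queries)
        _write_fasta(spath, subjects)
        cmd = [
            program, "-query", str(qpath), "-subject", str(spath),
            "-outfmt", _OUTFMT, "-evalue", str(evalue),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True, check=True)
    hits: list[LocalAlignment] = []
    for line in proc.stdout.splitlines():
        if not line.strip():
            continue
        qid, sid, pident, length, qs, qe, ss, se, _ev, bits = line.split("\t")
        qlen = len(queries[qid])
        slen = len(subjects[sid])
        q_span = (int(qs) - 1, int(qe))
        s0, s1 = int(ss), int(se)
        if s0 > s1:  # minus-strand hit: normalize to forward coordinates
            s0, s1 = s1, s0
        s_span = (s0 - 1, s1)
        hits.append(
            LocalAlignment(
                query_id=qid,
                subject_id=sid,
                score=round(float(bits)),
                identity_pct=float(pident),
                alignment_length=int(length),
                query_span=q_span,
                subject_span=s_span,
                query_coverage=(q_span[1] - q_span[0]) / qlen,
                subject_coverage=(s_span[1] - s_span[0]) / slen,
            )
        )
    return hits
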