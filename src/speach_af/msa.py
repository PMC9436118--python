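"""a3m alignment parsing and in-silico alanine mutagenesis.

a3m (MMseqs2/ColabFold dialect): the first sequence is the query, uppercase
and gapless.  In every other sequence an uppercase letter or ``'-'`` occupies
a *match column* (one per query position, in order) while lowercase letters
are insertions relative to the query and have no query equivalent; ``'.'``
characters, when present (HH-suite exports), are insertion placeholders and
are likewise skipped.  Hence for every entry::

    count(uppercase) + count('-') == len(query)

Mutagenesis replaces the match column of each selected query position with
alanine (or another residue) across *all* sequences — including the query
row, whose mutant is what gets folded — except where that column holds a
gap, which is left untouched.  Erasing a contact's residues across the whole
alignment removes its co-evolution signal, which is what nudges the predictor
toward conformations supported by the remaining covariation.

Parsing is byte-preserving outside edited columns: headers, entry order,
ColabFold ``#`` pairing metadata and every untouched character round-trip
exactly (one sequence line per entry).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from speach_af.contact_scan import MutationSet

__all__ = ["A3MAlignment", "read_a3m", "write_a3m", "mutate", "emit_campaign"]


def _match_column_count(seq: str) -> int:
    return sum(1 for c in seq if c == "-" or (c.isalpha() and c.isupper()))


def _match_column_char_indices(seq: str) -> list[int]:
    """Character index of each match column of ``seq`` (lowercase/'.' skipped)."""
    idx = []
    for i, c in enumerate(seq):
        if c == "-" or (c.isalpha() and c.isupper()):
            idx.append(i)
    return idx


@dataclass
class A3MAlignment:
    """An a3m alignment; ``entries[0]`` is the query row."""

    entries: list[tuple[str, str]]  # (header without '>', sequence)
    preamble: list[str] = field(default_factory=list)  # e.g. ColabFold '#' line(s)

    @property
    def query_id(self) -> str:
        return self.entries[0][0].split()[0]

    @property
    def query(self) -> str:
        return self.entries[0][1]

    @property
    def depth(self) -> int:
        return len(self.entries)

    def validate(self) -> None:
        if not self.entries:
            raise ValueError("alignment has no sequences")
        q = self.query
        if not q:
            raise ValueError("empty query sequence")
        if any(c == "-" or c.islower() for c in q):
            raise ValueError("query row must be uppercase and gapless")
        L = len(q)
        for header, seq in self.entries:
            n = _match_column_count(seq)
            if n != L:
                raise ValueError(
                    f"entry {header!r}: {n} match columns "
                    f"(uppercase + '-'), expected {L} (query length)"
                )


def read_a3m(path: str | Path) -> A3MAlignment:
    """Parse an a3m file; hard error naming any entry that violates
    match-column conservation."""
    path = Path(path)
    text = path.read_text()
    preamble: list[str] = []
    entries: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        if header is None and not entries and not line.startswith(">"):
            if line.strip():
                preamble.append(line)
            continue
        if line.startswith(">"):
            if header is not None:
                entries.append((header, "".join(chunks)))
            header = line[1:]
            chunks = []
        else:
            chunks.append(line.strip())
    if header is not None:
        entries.append((header, "".join(chunks)))
    if not entries:
        raise ValueError(f"{path}: no sequences found")
    aln = A3MAlignment(entries=entries, preamble=preamble)
    aln.validate()
    return aln


def write_a3m(aln: A3MAlignment, path: str | Path) -> None:
    lines = list(aln.preamble)
    for header, seq in aln.entries:
        lines.append(">" + header)
        lines.append(seq)
    Path(path).write_text("\n".join(lines) + "\n")


def mutate(
    aln: A3MAlignment, mset: MutationSet, to_residue: str = "A"
) -> A3MAlignment:
    """Substitute ``to_residue`` at the selected match columns of every entry.

    Gap columns ('-') are left untouched; insertions (lowercase, '.') are
    never modified; every character outside the selected match columns is
    byte-identical to the input.  Idempotent.
    """
    if len(to_residue) != 1 or not to_residue.isalpha():
        raise ValueError(f"to_residue must be a single letter, got {to_residue!r}")
    sub = to_residue.upper()
    L = len(aln.query)
    bad = [p for p in mset.positions if not (1 <= p <= L)]
    if bad:
        raise ValueError(f"positions beyond query length {L}: {bad}")
    new_entries = []
    for header, seq in aln.entries:
        cols = _match_column_char_indices(seq)
        chars = list(seq)
        for pos in mset.positions:
            i = cols[pos - 1]
            if chars[i] != "-":
                chars[i] = sub
        new_entries.append((header, "".join(chars)))
    return A3MAlignment(entries=new_entries, preamble=list(aln.preamble))


def emit_campaign(
    aln: A3MAlignment,
    sets: list[MutationSet],
    out_dir: str | Path,
    runs_per_set: int = 3,
    models_per_run: int = 5,
    to_residue: str = "A",
) -> dict:
    """Write one mutated a3m (and mutant-query FASTA) per mutation set, plus
    the unmodified alignment, and a JSON manifest of the planned folding runs.

    Each alignment is planned for ``runs_per_set`` folding runs of
    ``models_per_run`` models (3 × 5 = 15 by default); the unmodified MSA is
    run the same number of times, so a campaign of *k* sets expects
    ``k × 15`` mutant models and ``(k + 1) × 15`` in total.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    msa_dir = out_dir / "msas"
    msa_dir.mkdir(exist_ok=True)

    ids = [s.set_id for s in sets]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate set_ids in campaign")
    empty = [s.set_id for s in sets if s.empty]
    if empty:
        raise ValueError(f"empty mutation sets cannot be folded: {empty}")

    entries = []
    unmod_path = msa_dir / "unmodified.a3m"
    write_a3m(aln, unmod_path)
    entries.append(
        {
            "set_id": "unmodified",
            "a3m": str(unmod_path),
            "query": aln.query,
            "positions": [],
            "runs_per_set": runs_per_set,
            "models_per_run": models_per_run,
        }
    )
    for mset in sets:
        mutated = mutate(aln, mset, to_residue=to_residue)
        a3m_path = msa_dir / f"{mset.set_id}.a3m"
        write_a3m(mutated, a3m_path)
        fasta_path = msa_dir / f"{mset.set_id}.fasta"
        fasta_path.write_text(f">{mutated.query_id}_{mset.set_id}\n{mutated.query}\n")
        entries.append(
            {
                "set_id": mset.set_id,
                "a3m": str(a3m_path),
                "fasta": str(fasta_path),
                "query": mutated.query,
                "positions": list(mset.positions),
                "runs_per_set": runs_per_set,
                "models_per_run": models_per_run,
            }
        )
    manifest = {
        "query_id": aln.query_id,
        "to_residue": to_residue,
        "n_sets": len(sets),
        "runs_per_set": runs_per_set,
        "models_per_run": models_per_run,
        "expected_mutant_models": len(sets) * runs_per_set * models_per_run,
        "expected_total_models": (len(sets) + 1) * runs_per_set * models_per_run,
        "entries": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
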