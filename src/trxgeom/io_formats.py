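"""File I/O: A3M/FASTA alignments, PDB backbones, template hit tables,
and the restraint archive.

Hit-table dialect (tab/whitespace separated, our own format; converting
native HHsearch ``.hhr`` output is a non-goal)::

    > <template_id> <probability%> <evalue>
    <query_pos> <template_pos> <confidence>
    ...
    > <next hit> ...

Positions are 1-based.  Restraints are stored as a compressed named-array
archive (``numpy`` ``.npz``) with keys ``dist``, ``omega``, ``theta``,
``phi`` following the trRosetta restraint convention.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence

from trxgeom import alphabet
from trxgeom.containers import MSA, BackboneStructure, GeometryPosterior, TemplateHit


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# A3M / FASTA
# ---------------------------------------------------------------------------

def read_a3m(path: str | Path) -> MSA:
    """Read an A3M or aligned-FASTA file into an :class:`MSA`.

    Lowercase letters (insertions relative to the query) and '.' are
    deleted from every row, so all returned rows share the query's length.
    Wildcard residues are kept in the rows but are treated as gap by every
    downstream statistic.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty alignment file")

    ids: list[str] = []
    raws: list[list[str]] = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith(">"):
            ids.append(line[1:].split()[0] if line[1:].split() else "")
            raws.append([])
        else:
            if not raws:
                raise ParseError(f"{path}: sequence data before first header")
            raws[-1].append(line)

    if not ids:
        raise ParseError(f"{path}: no FASTA records found")

    rows: list[str] = []
    for name, chunks in zip(ids, raws):
        seq = "".join(chunks)
        # A3M convention: lowercase = insertion relative to query; drop it.
        norm = "".join(c for c in seq if not (c.islower() or c == "."))
        for c in norm:
            if not alphabet.is_legal(c):
                raise ParseError(
                    f"{path}: record {name!r} contains illegal character {c!r}"
                )
        rows.append(norm)

    L = len(rows[0])
    for name, row in zip(ids, rows):
        if len(row) != L:
            raise ParseError(
                f"{path}: record {name!r} normalizes to length {len(row)}, "
                f"query has length {L}"
            )
    if alphabet.GAP in rows[0]:
        raise ParseError(f"{path}: query row contains gaps after normalization")
    return MSA(ids=ids, rows=rows)


def write_a3m(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(msa.ids, msa.rows):
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# PDB backbones
# ---------------------------------------------------------------------------

_BACKBONE_ATOMS = ("N", "CA", "C", "CB")


def read_backbone(path: str | Path, chain: str | None = None) -> BackboneStructure:
    """Read backbone N/CA/C/CB coordinates of one chain from a PDB file.

    Altloc conflicts resolve to the first occurrence; residues without a CA
    are dropped with a warning.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    try:
        atoms = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:  # pragma: no cover - biotite internal variants
        raise ParseError(f"{path}: cannot parse PDB structure: {exc}") from exc
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise ParseError(f"{path}: no ATOM records")
    if chain is not None:
        atoms = atoms[atoms.chain_id == chain]
        if atoms.array_length() == 0:
            raise ParseError(f"{path}: chain {chain!r} has no ATOM records")
    else:
        first_chain = atoms.chain_id[0]
        atoms = atoms[atoms.chain_id == first_chain]

    atoms = atoms[np.isin(atoms.atom_name, _BACKBONE_ATOMS)]

    coords: dict[int, dict[str, np.ndarray]] = {}
    resname: dict[int, str] = {}
    for i in range(atoms.array_length()):
        rid = int(atoms.res_id[i])
        name = str(atoms.atom_name[i])
        xyz = atoms.coord[i]
        entry = coords.setdefault(rid, {})
        if name in entry:
            if not np.allclose(entry[name], xyz, atol=1e-6):
                raise ParseError(
                    f"{path}: duplicate residue {rid} atom {name} with "
                    "conflicting coordinates"
                )
            continue
        entry[name] = xyz
        resname.setdefault(rid, str(atoms.res_name[i]))

    residue_ids = sorted(coords)
    kept: list[int] = []
    for rid in residue_ids:
        if "CA" not in coords[rid]:
            warnings.warn(f"{path}: residue {rid} lacks CA; dropped")
            continue
        kept.append(rid)
    if not kept:
        raise ParseError(f"{path}: no residues with CA atoms")

    L = len(kept)
    out = {name: np.full((L, 3), np.nan) for name in _BACKBONE_ATOMS}
    seq = []
    for k, rid in enumerate(kept):
        for name in _BACKBONE_ATOMS:
            if name in coords[rid]:
                out[name][k] = coords[rid][name]
        try:
            seq.append(ProteinSequence.convert_letter_3to1(resname[rid]))
        except Exception:
            seq.append("X")
    return BackboneStructure(
        residue_index=np.asarray(kept, dtype=np.int64),
        sequence="".join(seq),
        n=out["N"],
        ca=out["CA"],
        c=out["C"],
        cb=out["CB"],
    )


def write_backbone(structure: BackboneStructure, path: str | Path,
                   chain: str = "A") -> None:
    """Write backbone atoms (skipping NaN entries) as a PDB file."""
    L = len(structure)
    records = []
    for i in range(L):
        aa1 = structure.sequence[i]
        try:
            res3 = ProteinSequence.convert_letter_1to3(aa1)
        except Exception:
            res3 = "UNK"
        for name, arr in (("N", structure.n), ("CA", structure.ca),
                          ("C", structure.c), ("CB", structure.cb)):
            if np.isnan(arr[i]).any():
                continue
            records.append((name, res3, int(structure.residue_index[i]), arr[i]))
    array = struc.AtomArray(len(records))
    for j, (name, res3, rid, xyz) in enumerate(records):
        array.chain_id[j] = chain
        array.res_id[j] = rid
        array.res_name[j] = res3
        array.atom_name[j] = name
        array.element[j] = name[0]
        array.coord[j] = xyz
    array.hetero[:] = False
    pdb = PDBFile()
    pdb.set_structure(array)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Template hit tables
# ---------------------------------------------------------------------------

def read_hits_table(path: str | Path) -> list[TemplateHit]:
    """Read template hits in the documented dialect; file order preserved.

    Confidences outside [0, 1] are clipped with a warning.  An empty table
    yields an empty list (the pipeline then runs FM-only).
    """
    path = Path(path)
    hits: list[TemplateHit] = []
    cur: dict | None = None

    def _finish(cur: dict) -> None:
        hits.append(TemplateHit(
            template_id=cur["id"],
            probability=cur["prob"],
            evalue=cur["evalue"],
            aligned_pairs=cur["pairs"],
            confidence=cur["conf"],
        ))

    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if cur is not None:
                _finish(cur)
            fields = line[1:].split()
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: hit header needs id, probability, evalue"
                )
            prob, ev = float(fields[1]), float(fields[2])
            if not 0.0 <= prob <= 100.0:
                raise ParseError(
                    f"{path}:{lineno}: probability {prob} outside [0, 100]"
                )
            if ev < 0:
                raise ParseError(f"{path}:{lineno}: negative E-value {ev}")
            cur = {"id": fields[0], "prob": prob, "evalue": ev,
                   "pairs": [], "conf": {}}
        else:
            if cur is None:
                raise ParseError(f"{path}:{lineno}: alignment line before header")
            fields = line.split()
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 'query_pos template_pos conf'"
                )
            q, t, conf = int(fields[0]), int(fields[1]), float(fields[2])
            if not 0.0 <= conf <= 1.0:
                warnings.warn(
                    f"{path}:{lineno}: confidence {conf} clipped to [0, 1]"
                )
                conf = min(max(conf, 0.0), 1.0)
            cur["pairs"].append((q, t))
            cur["conf"][q] = conf
    if cur is not None:
        _finish(cur)
    return hits


def write_hits_table(hits: list[TemplateHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(f"> {hit.template_id} {hit.probability:g} {hit.evalue:g}\n")
            for q, t in hit.aligned_pairs:
                fh.write(f"{q}\t{t}\t{hit.confidence.get(q, 0.0):.6f}\n")


# ---------------------------------------------------------------------------
# Restraint archives
# ---------------------------------------------------------------------------

def write_restraints(posterior: GeometryPosterior, path: str | Path) -> None:
    """Write a posterior as a compressed named-array archive.

    Keys are ``dist``, ``omega``, ``theta``, ``phi``; round-tripping through
    :func:`read_restraints` reproduces the arrays bit-exactly.
    """
    posterior.check_normalized(atol=1e-4)
    np.savez_compressed(
        path,
        dist=posterior.dist,
        omega=posterior.omega,
        theta=posterior.theta,
        phi=posterior.phi,
    )


def read_restraints(path: str | Path) -> GeometryPosterior:
    with np.load(path) as archive:
        missing = {"dist", "omega", "theta", "phi"} - set(archive.files)
        if missing:
            raise ParseError(f"{path}: archive misses keys {sorted(missing)}")
        return GeometryPosterior(
            dist=archive["dist"],
            omega=archive["omega"],
            theta=archive["theta"],
            phi=archive["phi"],
        )
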