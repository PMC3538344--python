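"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
* genotype TSV — header ``marker_id  seg_type  <ind1> <ind2> ...``; one row
  per marker with per-individual cells ``code:depthA,depthB`` and
  ``--:0,0`` for missing calls.
* JoinMap-style ``.loc`` — population type F2, codes a/h/b/c/d and ``-``.
* map TSV — group, rank, marker_id, position_cM (2 decimals).
* lengths TSV — reference sequence id, length.
* truth TSVs for the simulator (true map, mutations, selection blocks).
* YAML simulation / pipeline configuration mirroring the dataclass fields.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .genotypes import CHAR_TO_CODE, CODE_TO_CHAR, GenotypeMatrix, MISSING
from .linkage import GeneticMap, LinkageGroupResult
from .sim import SelectionBlock, SimConfig, TrueMap


class FormatError(ValueError):
    """Malformed input file; the message cites the offending line."""


# ---------------------------------------------------------------------------
# genotype TSV
# ---------------------------------------------------------------------------

def write_genotype_tsv(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tseg_type\t"
                 + "\t".join(str(i) for i in matrix.individual_ids) + "\n")
        for i in range(matrix.n_markers):
            cells = []
            for j in range(matrix.n_individuals):
                code = matrix.codes[i, j]
                ch = "--" if code == MISSING else CODE_TO_CHAR[int(code)]
                cells.append(
                    f"{ch}:{matrix.depth_a[i, j]},{matrix.depth_b[i, j]}")
            fh.write(f"{matrix.marker_ids[i]}\t{matrix.seg_types[i]}\t"
                     + "\t".join(cells) + "\n")


def read_genotype_tsv(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[:2] != ["marker_id", "seg_type"]:
            raise FormatError(f"{path}: bad header at line 1")
        individuals = header[2:]
        marker_ids, seg_types, codes, da, db = [], [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(individuals) + 2:
                raise FormatError(
                    f"{path}: wrong field count at line {lineno}")
            marker_ids.append(parts[0])
            seg_types.append(parts[1])
            crow, darow, dbrow = [], [], []
            for cell in parts[2:]:
                try:
                    code_s, depth_s = cell.split(":")
                    a_s, b_s = depth_s.split(",")
                    depth_pair = (int(a_s), int(b_s))
                except ValueError:
                    raise FormatError(
                        f"{path}: malformed cell {cell!r} at line {lineno}")
                if code_s == "--":
                    crow.append(MISSING)
                elif code_s in CHAR_TO_CODE and code_s != "-":
                    crow.append(CHAR_TO_CODE[code_s])
                else:
                    raise FormatError(
                        f"{path}: unknown genotype code {code_s!r} "
                        f"at line {lineno}")
                darow.append(depth_pair[0])
                dbrow.append(depth_pair[1])
            codes.append(crow)
            da.append(darow)
            db.append(dbrow)
    return GenotypeMatrix(marker_ids, individuals, seg_types,
                          np.array(codes, dtype=np.int8),
                          np.array(da, dtype=np.int32),
                          np.array(db, dtype=np.int32))


# ---------------------------------------------------------------------------
# JoinMap-style .loc
# ---------------------------------------------------------------------------

def write_loc(matrix: GenotypeMatrix, path, name: str = "radmap") -> None:
    """Locus file: genotype codes only (depths are not representable)."""
    with open(path, "w") as fh:
        fh.write(f"name = {name}\n")
        fh.write("popt = F2\n")
        fh.write(f"nloc = {matrix.n_markers}\n")
        fh.write(f"nind = {matrix.n_individuals}\n\n")
        for i in range(matrix.n_markers):
            row = " ".join(CODE_TO_CHAR[int(c)] for c in matrix.codes[i])
            fh.write(f"{matrix.marker_ids[i]}\t{row}\n")


def read_loc(path) -> GenotypeMatrix:
    """Parse a locus file into a depth-less genotype matrix.

    Segregation types are not encoded in this dialect; they are set
    ``unknown`` and can be refined from parental genotypes.
    """
    meta: dict[str, str] = {}
    marker_ids, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(";"):
                continue
            if "=" in s and len(s.split("=")[0].split()) == 1:
                key, _, val = s.partition("=")
                meta[key.strip().lower()] = val.strip()
                continue
            parts = s.split()
            marker, cells = parts[0], parts[1:]
            try:
                rows.append([CHAR_TO_CODE[c] for c in cells])
            except KeyError as exc:
                raise FormatError(
                    f"{path}: unknown genotype code {exc.args[0]!r} "
                    f"at line {lineno}")
            marker_ids.append(marker)
    if meta.get("popt", "F2").upper() != "F2":
        raise FormatError(f"{path}: population type must be F2")
    if not rows:
        raise FormatError(f"{path}: no marker rows")
    width = {len(r) for r in rows}
    if len(width) != 1:
        raise FormatError(f"{path}: ragged genotype rows")
    n = width.pop()
    if "nind" in meta and int(meta["nind"]) != n:
        raise FormatError(f"{path}: nind does not match genotype columns")
    individuals = [f"ind{j + 1}" for j in range(n)]
    return GenotypeMatrix(marker_ids, individuals, ["unknown"] * len(rows),
                          np.array(rows, dtype=np.int8))


# ---------------------------------------------------------------------------
# map / lengths / misc tables
# ---------------------------------------------------------------------------

def write_map(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False,
                           float_format="%.2f")


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    groups = []
    for gid, sub in df.groupby("group", sort=False):
        sub = sub.sort_values("rank")
        groups.append(LinkageGroupResult(
            str(gid), [str(m) for m in sub.marker_id],
            sub.position_cM.to_numpy(dtype=float)))
    return GeneticMap(groups)


def read_lengths(path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: expected 2 columns at line {lineno}")
            try:
                out[parts[0]] = float(parts[1])
            except ValueError:
                raise FormatError(
                    f"{path}: bad length {parts[1]!r} at line {lineno}")
    return out


def write_true_map(true_map: TrueMap, path) -> None:
    true_map.to_frame().to_csv(path, sep="\t", index=False)


def write_mutation_truth(mutations: pd.DataFrame, path) -> None:
    mutations.to_csv(path, sep="\t", index=False)


def write_selection_blocks(blocks: list[SelectionBlock], path) -> None:
    pd.DataFrame([b.__dict__ for b in blocks]).to_csv(path, sep="\t",
                                                      index=False)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def read_sim_config(path) -> SimConfig:
    """Build a SimConfig from a YAML file mirroring its field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: expected a mapping at top level")
    if "distortion_blocks" in raw and raw["distortion_blocks"] is not None:
        raw["distortion_blocks"] = [
            SelectionBlock(**b) if isinstance(b, dict)
            else SelectionBlock(*b)
            for b in raw["distortion_blocks"]
        ]
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return SimConfig(**raw)


def write_sim_config(config: SimConfig, path) -> None:
    data = {k: getattr(config, k)
            for k in SimConfig.__dataclass_fields__}
    data["distortion_blocks"] = [dict(b.__dict__)
                                 for b in config.distortion_blocks]
    data["group_lengths_cm"] = [float(x) for x in config.group_lengths_cm]
    data["markers_per_group"] = [int(x) for x in config.markers_per_group]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
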