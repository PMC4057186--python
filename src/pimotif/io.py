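"""Readers and writers for the standard formats touched by the workflow.

FASTA fragments (gzip-transparent, biopython), JASPAR/TRANSFAC/plain motif
matrices, BED6 site exports, JSON model documents, and TSV matrix/trace
exports.  BED coordinates are 0-based half-open; logged positions are
1-based.
"""
from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .core import PWM, Fragment, PIMParams
from .mixture import MixtureModel

_VALID = set("ACGTN")


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[Fragment]:
    """Ordered fragments from a (possibly gzipped) FASTA file.

    Lowercase is accepted as sequence; N marks masked bases; any other
    symbol raises an error naming the offending record.
    """
    fragments = []
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            seq = str(record.seq).upper()
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"record {record.id!r}: invalid character(s) "
                    f"{sorted(bad)}"
                )
            fragments.append(Fragment(record.id, seq))
    if not fragments:
        raise ValueError(f"no FASTA records found in {path}")
    return fragments


def write_fasta(fragments: list[Fragment], path) -> None:
    with _open_text(path, "wt") as out:
        for frag in fragments:
            out.write(f">{frag.id}\n")
            for k in range(0, len(frag.sequence), 70):
                out.write(frag.sequence[k:k + 70] + "\n")


# ---------------------------------------------------------------------------
# motif matrices


def _counts_to_pwm(counts: np.ndarray, beta: float) -> PWM:
    counts = np.asarray(counts, dtype=np.float64)
    if counts.min() < 0:
        raise ValueError("negative matrix entries")
    num = counts + beta
    return PWM(num / num.sum(axis=1, keepdims=True), beta=beta)


def _parse_jaspar(text: str) -> np.ndarray:
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(">"):
            continue
        line = line.replace("[", " ").replace("]", " ")
        parts = line.split()
        if parts and parts[0].upper() in "ACGT" and len(parts[0]) == 1:
            parts = parts[1:]
        rows.append([float(x) for x in parts])
    if len(rows) != 4:
        raise ValueError(f"expected 4 nucleotide rows, found {len(rows)}")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("inconsistent row lengths")
    return np.array(rows).T  # (L, 4)


def _parse_transfac(text: str) -> np.ndarray:
    rows = []
    in_matrix = False
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        tag = parts[0].upper()
        if tag in ("P0", "PO"):
            in_matrix = True
            continue
        if in_matrix and tag.isdigit():
            if len(parts) < 5:
                raise ValueError(f"malformed TRANSFAC row: {line!r}")
            rows.append([float(x) for x in parts[1:5]])
        elif in_matrix and tag in ("XX", "//"):
            break
    if not rows:
        raise ValueError("no TRANSFAC matrix rows found")
    return np.array(rows)  # (L, 4)


def _parse_plain(text: str) -> np.ndarray:
    rows = [[float(x) for x in line.split()]
            for line in text.splitlines() if line.strip()
            and not line.lstrip().startswith("#")]
    arr = np.array(rows)
    if arr.ndim != 2:
        raise ValueError("malformed plain matrix")
    if arr.shape[1] != 4 and arr.shape[0] == 4:
        arr = arr.T
    if arr.shape[1] != 4:
        raise ValueError("plain matrix must have 4 columns (A C G T)")
    return arr


def read_matrix(path, dialect: str = "jaspar_pfm", beta: float = 0.0) -> PWM:
    """Read a motif matrix and normalize to an (L, 4) probability PWM.

    Count-valued matrices are converted with pseudo-count ``beta``;
    probability-valued matrices (rows summing to 1) pass through unchanged
    when ``beta`` is 0.
    """
    with _open_text(path) as fh:
        text = fh.read()
    if dialect == "jaspar_pfm":
        arr = _parse_jaspar(text)
    elif dialect == "transfac":
        arr = _parse_transfac(text)
    elif dialect == "plain":
        arr = _parse_plain(text)
    else:
        raise ValueError("dialect must be jaspar_pfm|transfac|plain")
    if beta == 0.0 and np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
        return PWM(arr / arr.sum(axis=1, keepdims=True))
    return _counts_to_pwm(arr, beta)


# ---------------------------------------------------------------------------
# model documents and tabular exports


def save_model(model, path, meta: dict | None = None) -> None:
    meta = dict(meta or {})
    meta.setdefault("tool", f"pimotif {__version__}")
    if isinstance(model, PIMParams):
        text = model.to_json(meta=meta)
    elif isinstance(model, MixtureModel):
        doc = json.loads(model.to_json())
        doc["meta"] = meta
        text = json.dumps(doc, sort_keys=True, indent=1)
    elif isinstance(model, PWM):
        text = json.dumps({"pwm": model.probs.tolist(), "beta": model.beta,
                           "meta": meta}, sort_keys=True, indent=1)
    else:
        raise TypeError(f"unsupported model type {type(model)!r}")
    Path(path).write_text(text + "\n")


def load_model(path):
    doc = json.loads(Path(path).read_text())
    if "couplings" in doc:
        return PIMParams.from_json(json.dumps(doc))
    if "components" in doc:
        return MixtureModel.from_json(json.dumps(doc))
    if "pwm" in doc:
        return PWM(np.array(doc["pwm"]), beta=doc.get("beta", 0.0))
    raise ValueError(f"unrecognized model document: {path}")


def write_bed(selected: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Selected sites as BED6 (0-based half-open; score = bits x 100).

    A sidecar ``<path>.meta.json`` records the tool version and run
    configuration.
    """
    frame = selected.copy()
    L = len(frame["site"].iloc[0]) if len(frame) else 0
    with open(path, "w") as out:
        for r in frame.itertuples():
            out.write(
                f"{r.fragment}\t{int(r.offset)}\t{int(r.offset) + L}\t"
                f"{r.site}\t{int(round(r.score * 100))}\t{r.strand}\n"
            )
    sidecar = {"tool": f"pimotif {__version__}", **(meta or {})}
    Path(str(path) + ".meta.json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1) + "\n")


def write_sites_text(selected: pd.DataFrame, path,
                     meta: dict | None = None) -> None:
    """Plain site list (one matched-orientation L-mer per line)."""
    with open(path, "w") as out:
        out.write(f"# pimotif {__version__}\n")
        for key, val in sorted((meta or {}).items()):
            out.write(f"# {key}: {val}\n")
        for site in selected["site"]:
            out.write(site + "\n")


def write_matrix_tsv(matrix: np.ndarray, path, label: str = "pos",
                     meta: dict | None = None) -> None:
    """L x L (or L x k) matrix as TSV with 1-based position headers."""
    arr = np.asarray(matrix)
    with open(path, "w") as out:
        out.write(f"# pimotif {__version__}\n")
        for key, val in sorted((meta or {}).items()):
            out.write(f"# {key}: {val}\n")
        header = "\t".join([label] + [str(j + 1) for j in range(arr.shape[1])])
        out.write(header + "\n")
        for i, row in enumerate(arr):
            out.write("\t".join([str(i + 1)] + [f"{v:.6g}" for v in row])
                      + "\n")
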