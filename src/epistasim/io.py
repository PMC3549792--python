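"""Persistence for penetrance models and simulated datasets.

Model files are line-oriented text: ``#``-prefixed ``key: value`` header
lines (loci count, MAFs, recomputed summary metrics, optional provenance)
followed by one ``<genotype-label><TAB><penetrance>`` line per MLG in
canonical order. Values are serialized with full float precision (repr), so
a write/read round trip is lossless. On read, the body is authoritative:
header metric values that disagree with recomputation by more than 1e-9 are
logged as warnings and overridden.

Dataset files are tab-delimited text: a header row of SNP names plus
``Class``, then one row per sample of {0,1,2} genotype codes and a {0,1}
class label.
"""

from __future__ import annotations

import logging
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import GenotypeDataset
from .exceptions import (
    DegenerateModelError,
    InvalidParameterError,
    ModelFileError,
    UndefinedCORError,
)
from .genetics import PenetranceModel, heritability, prevalence
from .metrics import cor, edm, ptv

__all__ = [
    "genotype_labels",
    "write_model",
    "read_model",
    "write_dataset",
    "read_dataset",
]

logger = logging.getLogger(__name__)

_GENOTYPE_CODES = ("{U}{U}", "{U}{l}", "{l}{l}")  # 0, 1, 2 minor alleles
_HEADER_TOL = 1e-9


def genotype_labels(n_loci: int) -> list[str]:
    """Canonical MLG labels: locus i uses the i-th alphabet letter, with
    genotype codes AA / Aa / aa (0, 1, 2 minor alleles). E.g. ``AaBB``."""
    if not (1 <= n_loci <= 26):
        raise InvalidParameterError("n_loci must lie in [1, 26] for labeling")
    per_locus = [
        [
            _GENOTYPE_CODES[g].format(U=chr(ord("A") + i), l=chr(ord("a") + i))
            for g in range(3)
        ]
        for i in range(n_loci)
    ]
    return ["".join(combo) for combo in product(*per_locus)]


def _summary_metrics(model: PenetranceModel) -> dict[str, str]:
    out: dict[str, str] = {"prevalence": repr(prevalence(model))}
    for name, fn in (
        ("heritability", heritability),
        ("edm", edm),
        ("cor", cor),
        ("ptv", ptv),
    ):
        try:
            out[name] = repr(fn(model))
        except (DegenerateModelError, UndefinedCORError):
            out[name] = "undefined"
    return out


def write_model(path, model: PenetranceModel, provenance: dict | None = None) -> None:
    """Write a model file with a recomputed metric header."""
    path = Path(path)
    lines = ["# epistasim penetrance model"]
    lines.append(f"# n_loci: {model.n_loci}")
    lines.append("# mafs: " + " ".join(repr(q) for q in model.mafs))
    for key, val in _summary_metrics(model).items():
        lines.append(f"# {key}: {val}")
    for key, val in (provenance or {}).items():
        lines.append(f"# {key}: {val}")
    labels = genotype_labels(model.n_loci)
    for label, f in zip(labels, model.penetrances):
        lines.append(f"{label}\t{float(f)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_model(path) -> PenetranceModel:
    """Read a model file; the penetrance body wins over stale header metrics."""
    path = Path(path)
    header: dict[str, str] = {}
    values: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
            continue
        fields = line.split()
        try:
            values.append(float(fields[-1]))
        except ValueError:
            raise ModelFileError(
                f"{path}:{lineno}: cannot parse penetrance value from {raw!r}"
            ) from None
    if "n_loci" not in header or "mafs" not in header:
        raise ModelFileError(f"{path}: missing required header keys n_loci / mafs")
    try:
        n_loci = int(header["n_loci"])
        mafs = tuple(float(tok) for tok in header["mafs"].split())
    except ValueError as exc:
        raise ModelFileError(f"{path}: malformed header: {exc}") from None
    if len(values) != 3**n_loci:
        raise ModelFileError(
            f"{path}: expected {3 ** n_loci} penetrance values for "
            f"{n_loci} loci, found {len(values)}"
        )
    try:
        model = PenetranceModel(mafs=mafs, penetrances=np.array(values))
    except InvalidParameterError as exc:
        raise ModelFileError(f"{path}: {exc}") from None
    _check_header_consistency(path, header, model)
    return model


def _check_header_consistency(path, header, model) -> None:
    recomputed = {"prevalence": prevalence, "heritability": heritability}
    for key, fn in recomputed.items():
        if key not in header or header[key] == "undefined":
            continue
        try:
            stated = float(header[key])
        except ValueError:
            continue
        try:
            actual = fn(model)
        except DegenerateModelError:
            continue
        if abs(stated - actual) > _HEADER_TOL:
            logger.warning(
                "%s: header %s = %s disagrees with recomputed %r; body wins",
                path,
                key,
                header[key],
                actual,
            )


def write_dataset(path, dataset: GenotypeDataset) -> None:
    """Write a dataset as tab-delimited text (SNP columns + Class)."""
    if dataset.n_samples == 0:
        raise InvalidParameterError(f"refusing to write empty dataset to {path}")
    dataset.to_dataframe().to_csv(path, sep="\t", index=False)


def read_dataset(path) -> GenotypeDataset:
    """Read a tab-delimited dataset file back into a :class:`GenotypeDataset`."""
    df = pd.read_csv(path, sep="\t")
    if "Class" not in df.columns:
        raise ModelFileError(f"{path}: missing Class column")
    labels = df.pop("Class").to_numpy(dtype=np.int64)
    return GenotypeDataset(
        genotypes=df.to_numpy(dtype=np.int8),
        class_labels=labels,
        snp_names=tuple(df.columns),
    )
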