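"""Readers, writers and run configuration.

Tabular data is plain TSV/CSV with a ``#``-comment provenance header
(tool version, seed, config hash); fits are JSON; model, demography and
synthesis specs are YAML or JSON.  GWAS input is a TSV with header
columns ``snp``, ``freq``, ``beta`` (and optionally ``var_explained``,
``n``); frequencies are stored as derived/effect-allele frequencies in
(0,1) — MAF folding happens only inside statistics, never in storage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import ModelParams, load_params
from .wrightfisher import Demography
from .inference import GWASTable, FitResult

logger = logging.getLogger("quantgen_arch")

__all__ = [
    "read_gwas_tsv", "write_gwas_tsv", "read_config", "read_demography",
    "write_fit_json", "read_fit_json", "provenance_header", "config_hash",
]

_REQUIRED = ("snp", "freq", "beta")


def read_gwas_tsv(path, V_P=None, h2=None, m=None) -> GWASTable:
    """Read a GWAS hit table; invalid rows are dropped and counted.

    Requires ``snp``, ``freq`` and either ``beta`` or ``var_explained``.
    Rows with frequency outside (0,1) or non-finite effects are dropped
    with a logged count.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    have_v = "var_explained" in df.columns
    missing = [c for c in _REQUIRED if c not in df.columns
               and not (c == "beta" and have_v)]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} "
                         f"(found {list(df.columns)})")
    table = GWASTable(frame=df, V_P=V_P, h2=h2, m=m)
    if table.n_dropped:
        logger.info("%s: dropped %d invalid row(s)", path, table.n_dropped)
    return table


def provenance_header(seed=None, config_hash_=None, extra=None) -> str:
    parts = [f"# quantgen-arch {__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    if config_hash_ is not None:
        parts.append(f"# config_hash: {config_hash_}")
    for k, v in (extra or {}).items():
        parts.append(f"# {k}: {v}")
    return "\n".join(parts) + "\n"


def write_gwas_tsv(table: GWASTable, path, seed=None) -> None:
    path = Path(path)
    header = provenance_header(
        seed=seed if seed is not None else table.metadata.get("seed"),
        config_hash_=table.metadata.get("spec_hash"),
        extra={k: v for k, v in table.metadata.items()
               if k not in ("seed", "spec_hash")},
    )
    with open(path, "w") as fh:
        fh.write(header)
        table.frame.to_csv(fh, sep="\t", index=False)


def write_table_csv(df: pd.DataFrame, path, seed=None, config_hash_=None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, config_hash_=config_hash_))
        df.to_csv(fh, index=False)


def config_hash(raw: dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()).hexdigest()[:12]


def read_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path} does not contain a mapping")
    return raw


def read_demography(path) -> Demography:
    return Demography.from_dict(read_config(path))


def write_fit_json(fit: FitResult, path, seed=None, config_hash_=None) -> None:
    payload = fit.to_dict()
    payload["_provenance"] = {"tool": f"quantgen-arch {__version__}",
                              "seed": seed, "config_hash": config_hash_}
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def read_fit_json(path) -> FitResult:
    raw = json.loads(Path(path).read_text())
    raw.pop("_provenance", None)
    ci = {k: tuple(v) for k, v in raw.pop("ci", {}).items()}
    fit = FitResult(
        vs=raw["vs"], vstar=raw["vstar"], n_loci=raw["n_loci"],
        mode=raw.get("mode", "pleiotropic-limit"),
        family=raw.get("family", "sites"), n_traits=raw.get("n_traits"),
        loglik=raw.get("loglik", np.nan), L=raw.get("L"),
        detectable_fraction=raw.get("detectable_fraction"),
        ks_D=raw.get("ks_D"), ks_p=raw.get("ks_p"), seed=raw.get("seed"),
    )
    fit.ci = ci
    return fit
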