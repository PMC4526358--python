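"""Plain-text serialization: scheme configs, trace tables, reports.

Schemes and spectral signatures travel as YAML key-value configs with
explicit keys (species list, per-transition k0/m_dagger, per-species
intercept/slope, temperature).  Kinetic traces, chevron datasets and
equilibrium curves are tab-separated tables; seeds and dead times are
recorded in ``#``-prefixed header lines so every output is reproducible
from its own metadata.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .kinetics import Constants, KineticScheme, SpectralSignature, UreaRateLaw
from .traces import KineticTrace

__all__ = [
    "write_scheme_config", "read_scheme_config",
    "write_traces", "read_traces",
    "write_table", "read_table",
    "write_fit_report", "read_fit_report",
]


def write_scheme_config(path, scheme: KineticScheme,
                        signature: SpectralSignature | None = None,
                        header: Mapping | None = None) -> None:
    doc = {
        "temperature_K": scheme.constants.temperature,
        "gas_constant_kcal": scheme.constants.gas_constant,
        "species": list(scheme.species),
        "transitions": {
            f"{a}->{b}": {"k0_per_s": float(law.k0),
                          "m_dagger_kcal_per_mol_M": float(law.m_dagger)}
            for (a, b), law in scheme.transitions.items()
        },
    }
    if signature is not None:
        doc["signature"] = {
            sp: {"intercept": float(i), "slope_per_M": float(s)}
            for sp, (i, s) in signature.values.items()
        }
    if header:
        doc["meta"] = dict(header)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_scheme_config(path) -> tuple[KineticScheme, SpectralSignature | None]:
    doc = yaml.safe_load(Path(path).read_text())
    constants = Constants(gas_constant=doc.get("gas_constant_kcal", Constants().gas_constant),
                          temperature=doc.get("temperature_K", Constants().temperature))
    laws = {}
    for key, val in doc["transitions"].items():
        a, b = key.split("->")
        laws[(a, b)] = UreaRateLaw(k0=float(val["k0_per_s"]),
                                   m_dagger=float(val["m_dagger_kcal_per_mol_M"]))
    scheme = KineticScheme(tuple(doc["species"]), laws, constants)
    signature = None
    if "signature" in doc:
        signature = SpectralSignature({
            sp: (float(v["intercept"]), float(v["slope_per_M"]))
            for sp, v in doc["signature"].items()
        })
    return scheme, signature


def _write_tsv(path, df: pd.DataFrame, header: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if "=" in line:
                k, v = line.lstrip("# ").split("=", 1)
                meta[k.strip()] = v.strip()
        else:
            lines.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(lines)), sep="\t")
    return df, meta


def write_traces(path, traces: Sequence[KineticTrace],
                 header: Mapping | None = None) -> None:
    """Trace table with columns time_s, fluorescence, urea_M, condition,
    dead_time_s; seed and design metadata go into ``#`` header lines."""
    frames = [
        pd.DataFrame({"time_s": tr.times, "fluorescence": tr.fluorescence,
                      "urea_M": tr.urea, "condition": tr.condition,
                      "dead_time_s": tr.dead_time})
        for tr in traces
    ]
    _write_tsv(path, pd.concat(frames, ignore_index=True), header)


def read_traces(path) -> list[KineticTrace]:
    df, _ = _read_tsv(path)
    out = []
    for (urea, cond, dead), grp in df.groupby(["urea_M", "condition", "dead_time_s"],
                                              sort=False):
        out.append(KineticTrace(times=grp["time_s"].to_numpy(),
                                fluorescence=grp["fluorescence"].to_numpy(),
                                urea=float(urea), dead_time=float(dead),
                                condition=str(cond)))
    return out


def write_table(path, df: pd.DataFrame, header: Mapping | None = None) -> None:
    """Generic delimited table (chevron, equilibrium, comparison...)."""
    _write_tsv(path, df, header)


def read_table(path) -> pd.DataFrame:
    return _read_tsv(path)[0]


def write_fit_report(path, estimates: Mapping[str, float],
                     stderr: Mapping[str, float] | None = None,
                     header: Mapping | None = None) -> None:
    """Key-value fit report: ``parameter\testimate\tstderr`` lines."""
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k} = {v}\n")
        fh.write("parameter\testimate\tstderr\n")
        for name, val in estimates.items():
            se = (stderr or {}).get(name, float("nan"))
            fh.write(f"{name}\t{val:.10g}\t{se:.6g}\n")


def read_fit_report(path) -> pd.DataFrame:
    return _read_tsv(path)[0]
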