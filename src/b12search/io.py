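"""Plain-text file formats used by the pipeline commands.

The query log is tab-separated (user_id, text, region), one event per line,
UTF-8; every reference table is comma-separated with a header; simulation
configs are YAML key: value files with a mandatory seed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .query_processing import TermLexicon
from .synthetic import IndicationSettings, SimulationConfig

LOG_COLUMNS = ["user_id", "text", "region"]


def write_log(events: pd.DataFrame, path: str | Path, header: bool = True) -> None:
    events[LOG_COLUMNS].to_csv(path, sep="\t", index=False, header=header)


def read_log(path: str | Path, header: bool = True) -> pd.DataFrame:
    if header:
        return pd.read_csv(path, sep="\t", dtype={"user_id": str})
    return pd.read_csv(path, sep="\t", names=LOG_COLUMNS, dtype={"user_id": str})


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"required input file not found: {path}")
    return pd.read_csv(path)


def read_lexicon(path: str | Path) -> TermLexicon:
    """Read a term lexicon CSV with columns ``term``, ``set`` (target/control)."""
    df = read_table(path)
    bad = set(df["set"]) - {"target", "control"}
    if bad:
        raise ValueError(f"lexicon 'set' column must be target/control, got {sorted(bad)}")
    return TermLexicon(
        target_terms=tuple(df.loc[df["set"] == "target", "term"]),
        control_terms=tuple(df.loc[df["set"] == "control", "term"]),
    )


def write_lexicon(lexicon: TermLexicon, path: str | Path) -> None:
    rows = [(t, "target") for t in lexicon.target_terms] + [
        (t, "control") for t in lexicon.control_terms
    ]
    pd.DataFrame(rows, columns=["term", "set"]).to_csv(path, index=False)


def read_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML file; ``seed`` is mandatory."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("config file must set an integer 'seed'")
    params = raw.pop("indication_params", None)
    if isinstance(params, dict) and "settings" in params:
        raw["indication_params"] = IndicationSettings(**params["settings"])
    elif isinstance(params, dict):
        raw["indication_params"] = {
            term: tuple(counts) for term, counts in params.items()
        }
    return SimulationConfig(**raw)


def write_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
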