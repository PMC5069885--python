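"""Plain-text readers/writers for the pipeline's tables.

Counts and tracks travel as headered TSV, states as 4-column BED
(0-based half-open, labels ``state_1`` .. ``state_9``), configuration as
YAML.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .simulate import SimConfig, SimulationResult, config_from_dict, config_to_dict


def read_counts(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    return df.set_index("barcode")["count"]


def write_counts(counts: pd.Series, path) -> None:
    counts.rename("count").rename_axis("barcode").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_mapping_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"barcode": str, "chrom": str})


def write_mapping_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_track(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_track(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False)


def read_barcode_list(path) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]


def load_config(path) -> SimConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def dump_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def write_outputs(sim: SimulationResult, outdir) -> None:
    """Write one simulated experiment as the pipeline's input files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(sim.config, out / "config.yaml")
    sim.states.to_bed(out / "states.bed")
    sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    write_mapping_records(sim.mapping_reads, out / "mapping_reads.tsv")
    write_track(sim.occupancy, out / "occupancy.tsv")
    write_counts(sim.spike_reference, out / "spike_gdna.tsv")
    for rep, tbl in sorted(sim.gdna.items()):
        write_counts(tbl, out / f"gdna_rep{rep}.tsv")
    for (cond, rep), tbl in sorted(sim.cdna.items()):
        write_counts(tbl, out / f"cdna_{cond}_rep{rep}.tsv")
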