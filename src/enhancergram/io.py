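"""Format plumbing: FASTA, profile TSV, BED, fit-result JSON, run manifests."""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .engine import N_POINTS, Profile
from .fitting import FitResult
from .motifs import BindingSite, SiteMap

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_profiles_tsv",
    "write_profiles_tsv",
    "write_sites_bed",
    "write_windows_bed",
    "save_fit",
    "load_fit",
    "write_manifest",
]


def read_fasta(path) -> dict[str, str]:
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")


def write_profiles_tsv(profiles: dict[str, Profile], path) -> None:
    """Serialize profiles as construct_id / point_index (1-17) / value / stderr."""
    rows = []
    for cid, prof in profiles.items():
        err = prof.stderr if prof.stderr is not None else np.full(N_POINTS, np.nan)
        for i in range(N_POINTS):
            rows.append((cid, i + 1, prof.values[i], err[i]))
    pd.DataFrame(rows, columns=["construct_id", "point_index", "value", "stderr"]) \
        .to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path) -> dict[str, Profile]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for cid, grp in df.groupby("construct_id", sort=False):
        grp = grp.sort_values("point_index")
        if len(grp) != N_POINTS:
            raise ValueError(f"construct {cid}: expected {N_POINTS} points, got {len(grp)}")
        err = grp["stderr"].to_numpy(float)
        out[str(cid)] = Profile(
            grp["value"].to_numpy(float),
            None if np.isnan(err).all() else np.nan_to_num(err),
            construct_id=str(cid),
        )
    return out


def write_sites_bed(sitemap: SiteMap, path) -> None:
    """6-column BED: name=TF, score=bits x 100 rounded, strand."""
    with open(path, "w") as fh:
        for s in sitemap.sites:
            fh.write(
                f"{sitemap.sequence_id}\t{s.start}\t{s.end}\t{s.tf}\t"
                f"{round(s.score * 100)}\t{s.strand}\n"
            )


def write_windows_bed(rows: list[dict], path) -> None:
    """BED rows for scan windows: chrom/start/end/pattern/peak-score/strand."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['pattern']}\t"
                f"{round(1000 * r.get('score', 0.0))}\t+\n"
            )


def save_fit(res: FitResult, path) -> None:
    Path(path).write_text(json.dumps(res.to_json(), indent=1))


def load_fit(path) -> FitResult:
    return FitResult.from_json(json.loads(Path(path).read_text()))


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_manifest(command: str, cfg: dict, outputs: list[str], path) -> None:
    """JSON record of a command invocation: inputs, seeds, config hash."""
    from . import __version__

    payload = {
        "command": command,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "outputs": outputs,
        "version": __version__,
        "python": sys.version.split()[0],
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
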