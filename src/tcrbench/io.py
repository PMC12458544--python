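"""File formats, run configuration and reporting artifacts.

TSV is the canonical interchange format (the de-facto convention for CDR3
tables): binding tables carry ``peptide  cdr3b  cdr3a  label  source``
columns (missing chain columns allowed), repertoires are one sequence per
line or FASTA, folds and metric tables are flat TSVs.  Every run directory
receives a manifest (config hash, seed, package version) sufficient to
reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .core import BindingRecord, GroupThresholds, Repertoire, TcrbenchError
from .curation import normalize_label
from .metrics import DEFAULT_K_GRID, BedrocParams
from .sampling import EvalFold, SamplingSpec

logger = logging.getLogger("tcrbench.io")


class IOError_(TcrbenchError):
    pass


# ---------------------------------------------------------------------------
# binding tables

def read_binding_table(path: str | Path) -> list[BindingRecord]:
    """Read a TSV/CSV binding table into records.

    Requires ``peptide`` and ``label`` columns plus at least one of
    ``cdr3b``/``cdr3a``; ``source`` is optional.  The separator is taken from
    the extension (.csv -> comma, otherwise tab).
    """
    path = Path(path)
    if not path.exists():
        raise IOError_(f"binding table not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = set(df.columns)
    if "peptide" not in cols or "label" not in cols or not ({"cdr3b", "cdr3a"} & cols):
        raise IOError_(
            f"{path}: need columns peptide, label and cdr3b and/or cdr3a; got {sorted(cols)}"
        )
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            BindingRecord(
                peptide=d["peptide"],
                cdr3_beta=d.get("cdr3b") or None,
                cdr3_alpha=d.get("cdr3a") or None,
                label=normalize_label(d["label"]),
                source=d.get("source", ""),
            )
        )
    return records


def write_binding_table(records: Sequence[BindingRecord], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "peptide": [r.peptide for r in records],
            "cdr3b": [r.cdr3_beta or "" for r in records],
            "cdr3a": [r.cdr3_alpha or "" for r in records],
            "label": [r.label for r in records],
            "source": [r.source for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# repertoires

def read_repertoire(path: str | Path, chain: str = "beta") -> Repertoire:
    """Read a repertoire from plain text (one sequence per line) or FASTA."""
    path = Path(path)
    if not path.exists():
        raise IOError_(f"repertoire file not found: {path}")
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        from Bio import SeqIO

        seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    else:
        with open(path) as fh:
            seqs = [line.strip() for line in fh if line.strip()]
    return Repertoire.from_iterable(seqs, chain=chain)


def write_repertoire(repertoire: Repertoire, path: str | Path, fasta: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if fasta:
            for i, seq in enumerate(repertoire.sequences):
                fh.write(f">seq{i}\n{seq}\n")
        else:
            fh.write("\n".join(repertoire.sequences) + "\n")


# ---------------------------------------------------------------------------
# ground truth

def write_truth(truth, path: str | Path) -> None:
    """Persist synthetic ground truth as a motif table."""
    df = pd.DataFrame(
        {
            "peptide": list(truth.motifs),
            "motif": [truth.motifs[p] for p in truth.motifs],
            "binder_threshold": truth.binder_threshold,
            "chain": truth.chain,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path):
    from .synthetic import GroundTruth

    path = Path(path)
    if not path.exists():
        raise IOError_(f"truth table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "motif": str})
    if df.empty:
        raise IOError_(f"truth table is empty: {path}")
    return GroundTruth(
        motifs=dict(zip(df["peptide"], df["motif"])),
        binder_threshold=float(df["binder_threshold"].iloc[0]),
        chain=str(df["chain"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# folds, metrics, curves

def write_folds(folds: Sequence[EvalFold], path: str | Path) -> None:
    rows = [
        {"fold_id": f.fold_id, "peptide": p, "tcr": t, "label": lab, "strategy": f.strategy}
        for f in folds
        for p, t, lab in f.pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_folds(path: str | Path) -> list[EvalFold]:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "tcr": str})
    folds = []
    for fid, sub in df.groupby("fold_id", sort=True):
        folds.append(
            EvalFold(
                fold_id=int(fid),
                pairs=tuple(zip(sub["peptide"], sub["tcr"], sub["label"])),
                strategy=str(sub["strategy"].iloc[0]),
            )
        )
    return folds


def write_metric_records(records, path: str | Path) -> None:
    from .evaluation import records_to_frame

    records_to_frame(list(records)).to_csv(path, sep="\t", index=False)


def write_curves(curves: Mapping[str, Sequence[tuple[float, float]]], out_dir: str | Path) -> None:
    """One two-column TSV per peptide: fraction examined, fraction recovered."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, (pep, pts) in enumerate(sorted(curves.items())):
        df = pd.DataFrame(pts, columns=["fraction_examined", "fraction_recovered"])
        df.to_csv(out_dir / f"curve_{pep}.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration and manifest

@dataclass
class RunConfig:
    """Everything one evaluation run needs, serializable to YAML."""

    records: str = ""
    repertoire: str = ""
    truth: str = ""
    scores: str = ""
    out_dir: str = "runs"
    scorer: str = "random"
    chain: str = "beta"
    seed: int = 0
    chunk_size: int = 10_000
    noise_sd: float = 0.05
    thresholds: GroupThresholds = field(default_factory=GroupThresholds)
    sampling: SamplingSpec = field(default_factory=SamplingSpec)
    bedroc: BedrocParams = field(default_factory=BedrocParams)
    k_grid: tuple[float, ...] = DEFAULT_K_GRID
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise IOError_(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        kwargs: dict = {}
        for key in (
            "records", "repertoire", "truth", "scores", "out_dir", "scorer",
            "chain", "seed", "chunk_size", "noise_sd", "synthetic",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "thresholds" in raw:
            kwargs["thresholds"] = GroupThresholds(**raw["thresholds"])
        if "sampling" in raw:
            kwargs["sampling"] = SamplingSpec(**raw["sampling"])
        if "bedroc" in raw:
            kwargs["bedroc"] = BedrocParams(**raw["bedroc"])
        if "k_grid" in raw:
            kwargs["k_grid"] = tuple(raw["k_grid"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_grid"] = list(self.k_grid)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def write_manifest(out_dir: str | Path, config: RunConfig, extra: Mapping | None = None) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "tcrbench_version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# plots (artifacts only; every plotted number also exists in a TSV)

def plot_enrichment(curves: Mapping[str, Sequence[tuple[float, float]]], path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for pep, pts in sorted(curves.items()):
        xs, ys = zip(*pts)
        ax.plot(xs, ys, alpha=0.5, lw=1)
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="random")
    ax.set_xlabel("fraction of ranked list examined")
    ax.set_ylabel("fraction of binders recovered")
    ax.set_title("Enrichment")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metric_box(df: pd.DataFrame, metric: str, path: str | Path) -> None:
    """Boxplot of a metric's fold values per group, from a metric-record frame."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = df[df["metric"] == metric]
    groups = sorted(sub["group"].unique())
    data = [sub[sub["group"] == g]["value"].to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel(metric)
    ax.set_title(f"{metric} by group")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
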