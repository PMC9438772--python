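"""Readers and writers for the package's plain-text interchange formats.

Counts are tab-separated with template IDs as row names and sample IDs as
columns; sample metadata is a TSV with columns sample_id, cycle, replicate;
trees are Newick; sequences FASTA; kinetic parameters a TSV of
template_id, lambda, theta_z.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from pcrbias.coda import ContrastBasis, CountExperiment
from pcrbias.kinetics import PCRParams


def read_count_experiment(
    counts_path: str | Path, metadata_path: str | Path
) -> CountExperiment:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "cycle", "replicate"}
    if not required <= set(meta.columns):
        raise ValueError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    meta = meta.set_index("sample_id")
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    meta = meta.loc[list(counts.columns)]
    return CountExperiment(
        counts=counts.to_numpy(int),
        cycles=meta["cycle"].to_numpy(int),
        replicates=meta["replicate"].to_numpy(),
        template_ids=tuple(counts.index.astype(str)),
        sample_ids=tuple(counts.columns.astype(str)),
    )


def write_count_experiment(
    exp: CountExperiment, counts_path: str | Path, metadata_path: str | Path
) -> None:
    exp.counts_frame().to_csv(counts_path, sep="\t")
    exp.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


def read_basis(newick_path: str | Path) -> ContrastBasis:
    return ContrastBasis.from_newick(newick_path)


def write_newick(basis: ContrastBasis, path: str | Path) -> None:
    Path(path).write_text(basis.to_newick() + "\n")


def read_sequences(fasta_path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def write_sequences(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_energies(path: str | Path) -> pd.Series:
    """Per-template secondary-structure free energies (kcal/mol) from TSV.

    Expects columns template_id and energy (header required).
    """
    frame = pd.read_csv(path, sep="\t")
    if not {"template_id", "energy"} <= set(frame.columns):
        raise ValueError("energy table must have columns template_id, energy")
    return frame.set_index("template_id")["energy"].astype(float)


def write_energies(energies: pd.Series | dict[str, float], path: str | Path) -> None:
    series = pd.Series(energies, name="energy")
    series.rename_axis("template_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_params(path: str | Path, basis: ContrastBasis) -> PCRParams:
    frame = pd.read_csv(path, sep="\t").set_index("template_id")
    frame = frame.loc[list(basis.leaf_order)]
    lam = frame["lambda"].to_numpy(float)
    theta_z = frame["theta_z"].to_numpy(float)
    sigma = np.full(basis.n_balances, 0.05)
    if "sigma" in frame.columns:  # per-balance sigma is not per-template; keep scalar
        sigma = np.full(basis.n_balances, float(frame["sigma"].iloc[0]))
    return PCRParams.from_theta_z(theta_z, lam, sigma, basis)


def write_params(params: PCRParams, basis: ContrastBasis, path: str | Path) -> None:
    pd.DataFrame(
        {
            "template_id": list(basis.leaf_order),
            "lambda": params.lambda_,
            "theta_z": params.theta_z,
        }
    ).to_csv(path, sep="\t", index=False)
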