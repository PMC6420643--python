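"""Seeded synthetic data emulating the shapes of a deaminase experiment.

The generator produces, from one seed: (a) per-sample pileup columns with a
low background C→T error rate plus true edits at a defined allele fraction,
(b) UMI read families with sequencing errors in both the UMI and the read,
and (c) the matching truth tables, so edit calling and tree building can be
scored for precision/recall without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    n_sites: int = 50
    n_samples: int = 4
    depth_mean: float = 100.0
    background_error: float = 0.002
    edited_vaf: float = 0.5
    edited_fraction: float = 0.2
    umi_length: int = 8
    n_molecules: int = 30
    reads_per_molecule: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_error", "edited_vaf", "edited_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")


def generate_fixture(spec: FixtureSpec) -> dict:
    """Deterministic fixture bundle.

    Returns a dict with keys:

    * ``pileups`` — sample_id -> list of (chrom, pos, ref, depth, alt)
      pileup rows (positions 1-based, all reference C);
    * ``truth`` — DataFrame (site_id, sample_id, edited);
    * ``umi_reads`` — DataFrame (read_id, umi, sequence) with molecule truth
      in ``umi_truth``;
    * ``barcodes`` — samples x sites 0/1 DataFrame of true edit states.
    """
    rng = np.random.default_rng(spec.seed)
    sites = [f"target:{i + 1}" for i in range(spec.n_sites)]
    samples = [f"S{j + 1}" for j in range(spec.n_samples)]

    edited = rng.random((spec.n_sites, spec.n_samples)) < spec.edited_fraction
    pileups: dict[str, list[tuple[str, int, str, int, int]]] = {}
    truth_rows = []
    for j, s in enumerate(samples):
        rows = []
        for i in range(spec.n_sites):
            depth = int(rng.poisson(spec.depth_mean))
            p = spec.edited_vaf if edited[i, j] else spec.background_error
            alt = int(rng.binomial(depth, p)) if depth else 0
            rows.append(("target", i + 1, "C", depth, alt))
            truth_rows.append(
                {"site_id": sites[i], "sample_id": s, "edited": bool(edited[i, j])}
            )
        pileups[s] = rows

    # UMI families: distinct true UMIs, constant-ish read counts, occasional
    # one-base UMI errors that create satellite families
    true_umis = [
        "".join(rng.choice(BASES, size=spec.umi_length)) for _ in range(spec.n_molecules)
    ]
    molecule_seq = [
        "".join(rng.choice(BASES, size=30)) for _ in range(spec.n_molecules)
    ]
    reads = []
    for m, (u, mseq) in enumerate(zip(true_umis, molecule_seq)):
        nreads = max(1, int(rng.poisson(spec.reads_per_molecule)))
        for r in range(nreads):
            umi = u
            if rng.random() < 0.1:  # sequencing error inside the UMI
                pos = int(rng.integers(spec.umi_length))
                repl = str(rng.choice([b for b in "ACGT" if b != u[pos]]))
                umi = u[:pos] + repl + u[pos + 1 :]
            seq = mseq
            if rng.random() < 0.1:  # read error
                pos = int(rng.integers(len(mseq)))
                repl = str(rng.choice([b for b in "ACGT" if b != mseq[pos]]))
                seq = mseq[:pos] + repl + mseq[pos + 1 :]
            reads.append(
                {"read_id": f"m{m}_r{r}", "umi": umi, "sequence": seq, "molecule": m}
            )
    umi_df = pd.DataFrame(reads)

    barcodes = pd.DataFrame(
        edited.T.astype(int), index=samples, columns=sites
    )
    return {
        "pileups": pileups,
        "truth": pd.DataFrame(truth_rows),
        "umi_reads": umi_df[["read_id", "umi", "sequence"]],
        "umi_truth": umi_df,
        "barcodes": barcodes,
        "sites": sites,
        "samples": samples,
    }


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Materialise the fixture to text files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fx = generate_fixture(spec)
    for s, rows in fx["pileups"].items():
        dio.write_pileup(rows, out / f"{s}.pileup")
    fx["truth"].to_csv(out / "truth.tsv", sep="\t", index=False)
    fx["umi_reads"].to_csv(out / "umi_reads.tsv", sep="\t", index=False)
    fx["barcodes"].to_csv(out / "barcodes.tsv", sep="\t")
    return fx
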