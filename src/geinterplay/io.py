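"""Plain-text readers and writers for the pipeline's tables.

Formats: predictor panels as TSV with a one-line role header, summary
statistics as five-column TSV (snp, a1, a2, r, n), genotypes as a TSV matrix,
LD blocks as BED-like three-column intervals over the SNP index, truth records
as JSON.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .lassosum import SummaryStatisticsSet
from .preprocess import PredictorPanel


def write_panel_tsv(path, panel: PredictorPanel) -> None:
    p = Path(path)
    roles = [panel.roles[c] for c in panel.data.columns] + ["meta"]
    with p.open("w") as fh:
        fh.write("#roles\t" + "\t".join(roles) + "\n")
        df = panel.data.copy()
        df["split"] = np.where(panel.train_mask, "train", "holdout")
        df.to_csv(fh, sep="\t", index=False)


def read_panel_tsv(path, outcome: pd.Series | None = None) -> PredictorPanel:
    p = Path(path)
    with p.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "#roles":
            raise ValueError("panel TSV must start with a #roles header line")
        df = pd.read_csv(fh, sep="\t")
    roles = dict(zip(df.columns, header[1:]))
    mask = (df.pop("split") == "train").to_numpy()
    roles.pop("split", None)
    return PredictorPanel(data=df, roles=roles, train_mask=mask, outcome=outcome)


def write_summary_stats_tsv(path, stats: SummaryStatisticsSet) -> None:
    stats.to_frame().to_csv(path, sep="\t", index=False)


def read_summary_stats_tsv(path) -> SummaryStatisticsSet:
    df = pd.read_csv(path, sep="\t")
    return SummaryStatisticsSet(
        snp_ids=df["snp"].to_numpy(dtype=object),
        effect_allele=df["a1"].to_numpy(dtype=object),
        other_allele=df["a2"].to_numpy(dtype=object),
        r=df["r"].to_numpy(dtype=float),
        n_discovery=int(df["n"].iloc[0]),
    )


def write_genotypes_tsv(path, genotypes: pd.DataFrame) -> None:
    genotypes.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_blocks_bed(path, blocks) -> None:
    with Path(path).open("w") as fh:
        for start, stop in blocks:
            fh.write(f"snp_index\t{start}\t{stop}\n")


def read_blocks_bed(path) -> list[tuple[int, int]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        _, start, stop = line.split("\t")
        out.append((int(start), int(stop)))
    return out


def write_truth_json(path, truth) -> None:
    Path(path).write_text(truth.to_json())
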