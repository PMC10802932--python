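"""Pathway database: ligand-receptor pairs plus downstream wiring.

Three CSV tables define the signaling knowledge the pipeline uses:

* lr_pairs.csv      ligand,receptor,pathway  — LR pairs annotated to a pathway
* receptor_tf.csv   receptor,tf              — receptor to transcription factor
* tf_target.csv     tf,target                — TF to target gene

Only direct edges from these tables are used; completeness of the wiring is
the caller's contract. Gene identifiers are opaque strings matched exactly
and case-sensitively against the expression dataset.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import LoadError, ValidationError

LR_COLUMNS = ["ligand", "receptor", "pathway"]
RTF_COLUMNS = ["receptor", "tf"]
TFT_COLUMNS = ["tf", "target"]


@dataclass
class PathwayDatabase:
    lr_pairs: pd.DataFrame
    receptor_tf: pd.DataFrame
    tf_target: pd.DataFrame

    @property
    def pathway_names(self) -> list[str]:
        return sorted(self.lr_pairs["pathway"].unique())

    def validate(self) -> None:
        for df, cols, name in (
            (self.lr_pairs, LR_COLUMNS, "lr_pairs"),
            (self.receptor_tf, RTF_COLUMNS, "receptor_tf"),
            (self.tf_target, TFT_COLUMNS, "tf_target"),
        ):
            missing = set(cols) - set(df.columns)
            if missing:
                raise ValidationError(f"{name} table lacks columns {sorted(missing)}")
        if self.lr_pairs.duplicated(subset=LR_COLUMNS).any():
            dups = self.lr_pairs[self.lr_pairs.duplicated(subset=LR_COLUMNS)]
            raise ValidationError(
                f"duplicate (ligand, receptor, pathway) rows: {dups.head(5).values.tolist()}"
            )
        orphan = set(self.receptor_tf["receptor"]) - set(self.lr_pairs["receptor"])
        if orphan:
            raise ValidationError(
                f"receptor_tf receptors absent from lr_pairs: {sorted(orphan)[:10]}"
            )

    def genes(self) -> dict[str, set[str]]:
        """All database genes grouped by role."""
        return {
            "ligand": set(self.lr_pairs["ligand"]),
            "receptor": set(self.lr_pairs["receptor"]),
            "tf": set(self.receptor_tf["tf"]),
            "target": set(self.tf_target["target"]),
        }

    def checksum(self) -> str:
        """Content hash over canonically sorted tables; identifies the database."""
        h = hashlib.sha256()
        for df, cols in (
            (self.lr_pairs, LR_COLUMNS),
            (self.receptor_tf, RTF_COLUMNS),
            (self.tf_target, TFT_COLUMNS),
        ):
            canon = df[cols].sort_values(cols).to_csv(index=False)
            h.update(canon.encode())
        return h.hexdigest()


def load_pathway_database(
    lr_path: str | Path, rtf_path: str | Path, tft_path: str | Path
) -> PathwayDatabase:
    """Read the three CSV tables (header row required, UTF-8)."""
    frames = []
    for path, cols in ((lr_path, LR_COLUMNS), (rtf_path, RTF_COLUMNS), (tft_path, TFT_COLUMNS)):
        df = pd.read_csv(path, dtype=str)
        if set(cols) - set(df.columns):
            raise LoadError(f"{path} lacks required columns {cols}")
        frames.append(df[cols])
    db = PathwayDatabase(*frames)
    db.validate()
    return db


def write_pathway_database(db: PathwayDatabase, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lr_pairs": outdir / "lr_pairs.csv",
        "receptor_tf": outdir / "receptor_tf.csv",
        "tf_target": outdir / "tf_target.csv",
    }
    db.lr_pairs.to_csv(paths["lr_pairs"], index=False, columns=LR_COLUMNS)
    db.receptor_tf.to_csv(paths["receptor_tf"], index=False, columns=RTF_COLUMNS)
    db.tf_target.to_csv(paths["tf_target"], index=False, columns=TFT_COLUMNS)
    return paths
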