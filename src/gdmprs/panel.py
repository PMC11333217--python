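"""SNP weight panels: the loci, effect alleles, and per-allele weights of a PRS.

A panel is the score definition — for each variant the allele whose dosage is
counted (the *effect allele*) and the per-allele log-odds weight from GWAS
summary statistics. The generator additionally needs an effect-allele
frequency per variant to simulate genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PANEL_COLUMNS = ["rsid", "chrom", "pos", "effect_allele", "other_allele", "weight"]

_BASES = {"A", "C", "G", "T"}


class PanelError(ValueError):
    """Raised for malformed SNP weight panels."""


@dataclass(frozen=True)
class SNPPanel:
    """A small panel of risk variants defining a weighted dosage score.

    Parameters
    ----------
    table
        One row per variant with columns ``rsid``, ``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``weight`` and optionally
        ``allele_freq`` (effect-allele frequency, used only for simulation).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in PANEL_COLUMNS if c not in t.columns]
        if missing:
            raise PanelError(f"panel is missing columns: {missing}")
        if t["rsid"].duplicated().any():
            dups = t.loc[t["rsid"].duplicated(), "rsid"].tolist()
            raise PanelError(f"duplicate rsids in panel: {dups}")
        if (t["effect_allele"] == t["other_allele"]).any():
            bad = t.loc[t["effect_allele"] == t["other_allele"], "rsid"].tolist()
            raise PanelError(f"effect allele equals other allele for: {bad}")
        for col in ("effect_allele", "other_allele"):
            bad = ~t[col].isin(_BASES)
            if bad.any():
                raise PanelError(
                    f"non-ACGT {col} for: {t.loc[bad, 'rsid'].tolist()}"
                )
        if not np.isfinite(t["weight"].to_numpy(float)).all():
            raise PanelError("panel weights must be finite")
        if "allele_freq" in t.columns:
            f = t["allele_freq"].to_numpy(float)
            ok = np.isnan(f) | ((f > 0.0) & (f < 1.0))
            if not ok.all():
                raise PanelError("allele_freq must lie strictly in (0, 1)")

    @property
    def rsids(self) -> list[str]:
        return self.table["rsid"].tolist()

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(float)

    @property
    def allele_freqs(self) -> np.ndarray:
        if "allele_freq" not in self.table.columns:
            raise PanelError("panel has no allele_freq column (needed for simulation)")
        f = self.table["allele_freq"].to_numpy(float)
        if np.isnan(f).any():
            raise PanelError("panel allele_freq contains missing values")
        return f

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SNPPanel":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def default_panel() -> SNPPanel:
    """The built-in five-variant GDM risk panel.

    The five loci (MTNR1B, CDKAL1, TCF7L2, CDKN2A/B, HKDC1 regions) are
    established GDM/T2D risk loci. The weights and effect-allele frequencies
    are ILLUSTRATIVE values chosen so the weighted dosage score of a simulated
    population has mean ~0.31 and SD ~0.08; they are not estimates from any
    published GWAS and must be replaced with real summary statistics before
    scoring real genotypes.
    """
    table = pd.DataFrame(
        {
            "rsid": ["rs10830963", "rs9348441", "rs7903146", "rs10811662", "rs9663238"],
            "chrom": ["11", "6", "10", "9", "10"],
            "pos": [92708710, 20686573, 114758349, 22134068, 70989918],
            "effect_allele": ["G", "A", "T", "G", "G"],
            "other_allele": ["C", "T", "C", "A", "A"],
            "weight": [0.0612, 0.0474, 0.0543, 0.0444, 0.0494],
            "allele_freq": [0.62, 0.58, 0.61, 0.57, 0.63],
        }
    )
    return SNPPanel(table)
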