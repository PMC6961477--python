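"""Taxa x cluster abundance tables and their transforms.

`AbundanceMatrix` holds raw per-species read counts for repeat clusters (the
phylogenetic character data before transformation); `CharacterMatrix` is the
transformed table fed to the parsimony machinery.  Both wrap a pandas
DataFrame with taxa as rows and cluster ids as columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix", "CharacterMatrix", "cube_root_transform"]

logger = logging.getLogger(__name__)

#: cube of 65 -- a count at this value transforms to exactly 65, the upper
#: end of the conventional continuous-character input range.
CUBE_ROOT_CEILING_COUNT = 65 ** 3


@dataclass
class AbundanceMatrix:
    """Raw taxa x clusters count table.

    data : DataFrame with taxa as the index (ordered) and cluster ids as
        columns, values are non-negative read counts.
    transformed : always False here; kept so downstream code can refuse
        transformed input where raw counts are required.
    """

    data: pd.DataFrame
    transformed: bool = False

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundance counts must be non-negative")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(df.astype(float))


@dataclass
class CharacterMatrix:
    """Transformed continuous character table for parsimony inference."""

    data: pd.DataFrame
    transform_tag: str = "raw"
    rescaled: bool = field(default=False)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def characters(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        """(n_taxa, n_characters) float array in taxon order."""
        return self.data.to_numpy(dtype=float)


def cube_root_transform(matrix: AbundanceMatrix | pd.DataFrame,
                        rescale: bool = False) -> CharacterMatrix:
    """Cube-root each abundance, mapping counts into a compact 0-65 range.

    Counts up to 274,625 (= 65^3) land in [0, 65], the range conventionally
    required for continuous-character parsimony input.  If ``rescale`` is
    set, values are additionally scaled linearly so the maximum is 65; this
    is only needed for matrices whose largest count exceeds 274,625 and is
    logged when applied.
    """
    df = matrix.data if isinstance(matrix, AbundanceMatrix) else matrix
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("cube-root transform requires non-negative counts")
    out = np.cbrt(arr)
    rescaled = False
    if rescale and out.size and out.max() > 0:
        if df.to_numpy().max() > CUBE_ROOT_CEILING_COUNT:
            logger.info("rescaling cube-root values linearly into [0, 65] "
                        "(max count %.0f exceeds %d)",
                        df.to_numpy().max(), CUBE_ROOT_CEILING_COUNT)
        out = out * (65.0 / out.max())
        rescaled = True
    return CharacterMatrix(
        pd.DataFrame(out, index=df.index, columns=df.columns),
        transform_tag="cube_root",
        rescaled=rescaled,
    )
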