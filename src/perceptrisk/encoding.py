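"""Signed dummy encoding: categorical answers -> the respondent risk vector.

Each item contributes a block of columns, one per response category.  The
chosen category's column carries that category's sign (-1, 0 or +1); every
other column in the block is 0.  A missing answer leaves the whole block at
zero, so it contributes nothing to the additive risk score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import Codebook
from .responses import ResponseTable


@dataclass
class RiskMatrix:
    """n x m signed dummy matrix over {-1, 0, +1}.

    Rows align with respondents, columns with ``codebook.dummy_columns``.
    """

    values: np.ndarray
    respondent_ids: list
    columns: list  # (item_id, category) pairs
    codebook: Codebook

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.columns, names=["item", "category"])
        return pd.DataFrame(self.values, index=self.respondent_ids, columns=cols)

    def item_block(self, item_id: str) -> np.ndarray:
        """The column block of one item (n x k_item view)."""
        idx = [i for i, (it, _) in enumerate(self.columns) if it == item_id]
        return self.values[:, idx]

    def decode_item(self, item_id: str) -> list:
        """Recover chosen categories from an item's block (None = no mark).

        Inverse of the encoding up to missingness: only nonzero-signed
        choices leave a mark, so a zero-signed choice decodes to None just
        like a genuinely missing answer (it carries no risk information).
        """
        item = self.codebook[item_id]
        block = self.item_block(item_id)
        out = []
        for row in block:
            nz = np.nonzero(row)[0]
            out.append(item.categories[nz[0]] if len(nz) else None)
        return out


def encode_risk_matrix(responses: ResponseTable, codebook: Codebook | None = None
                       ) -> RiskMatrix:
    """Encode validated responses into the signed dummy risk matrix.

    Note that a chosen category whose sign is 0 leaves its block all-zero,
    exactly like a missing answer: the encoding is invertible up to
    missingness only over nonzero-signed choices, and the risk score is
    unaffected either way.
    """
    codebook = codebook or responses.codebook
    n = len(responses)
    m = codebook.n_dummies
    values = np.zeros((n, m), dtype=np.int8)

    col_offset = 0
    for item in codebook.items:
        answers = responses.data[item.item_id]
        cat_index = {c: i for i, c in enumerate(item.categories)}
        signs = np.array([item.sign_map[c] for c in item.categories], dtype=np.int8)
        codes = answers.map(cat_index)
        chosen = codes.notna().to_numpy()
        idx = codes[chosen].astype(int).to_numpy()
        rows = np.nonzero(chosen)[0]
        values[rows, col_offset + idx] = signs[idx]
        col_offset += len(item.categories)

    return RiskMatrix(
        values=values,
        respondent_ids=list(responses.respondent_ids),
        columns=codebook.dummy_columns,
        codebook=codebook,
    )
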