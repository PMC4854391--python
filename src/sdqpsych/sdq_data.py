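"""SDQ item structure, item-response I/O, scale scoring and endorsement rates.

The SDQ has 25 items in five subscales (emotional symptoms, conduct
problems, hyperactivity/inattention, peer problems, prosocial behaviour),
each answered on a three-point ordinal scale: 0 = "Not true",
1 = "Somewhat true", 2 = "Certainly true". Five positively worded problem
items (obeys, reflective, attends, friend, popular) are reverse scored so
that higher always means more problems on the four problem subscales;
prosocial items are positively worded but kept as-is (higher = more
prosocial).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .published import FACTORS, ITEM_ORDER, REVERSE_SCORED

SCALES = FACTORS
PROBLEM_SCALES = ("emotion", "conduct", "hyper", "peer")

#: integer code used internally for a missing response
MISSING = -1


@dataclass(frozen=True)
class SdqItemMeta:
    """Metadata for one SDQ item."""

    item_id: str
    scale: str
    positively_worded: bool
    reverse_scored: bool


def _build_items() -> tuple[SdqItemMeta, ...]:
    positively_worded = set(REVERSE_SCORED) | {
        "considerate", "shares", "caring", "kind", "helpout"}
    items = []
    for k, item in enumerate(ITEM_ORDER):
        scale = FACTORS[k // 5]
        items.append(SdqItemMeta(
            item_id=item,
            scale=scale,
            positively_worded=item in positively_worded,
            reverse_scored=item in REVERSE_SCORED,
        ))
    return tuple(items)


SDQ_ITEMS: tuple[SdqItemMeta, ...] = _build_items()
ITEM_INDEX = {m.item_id: k for k, m in enumerate(SDQ_ITEMS)}


def scale_items(scale: str) -> list[str]:
    """Item ids belonging to one subscale, in canonical order."""
    return [m.item_id for m in SDQ_ITEMS if m.scale == scale]


class ValidationError(ValueError):
    """Raised when an item-response table violates the SDQ coding contract."""


@dataclass
class ItemResponseMatrix:
    """Persons x 25 ordinal item responses with a two-level grouping variable.

    ``responses`` holds values in {0, 1, 2} with ``-1`` marking a missing
    cell. ``group`` holds one label per person. Raw (un-reversed) responses
    are stored; reversal of the positively worded problem items happens
    inside scoring / modeling.
    """

    responses: np.ndarray
    group: np.ndarray
    items: tuple[str, ...] = field(default=ITEM_ORDER)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.int64)
        self.group = np.asarray(self.group)
        if self.responses.ndim != 2 or self.responses.shape[1] != len(self.items):
            raise ValidationError(
                f"responses must be persons x {len(self.items)}, "
                f"got shape {self.responses.shape}")
        if self.group.shape[0] != self.responses.shape[0]:
            raise ValidationError("group labels must match number of persons")
        bad = ~np.isin(self.responses, (MISSING, 0, 1, 2))
        if bad.any():
            row = int(np.argwhere(bad)[0, 0])
            raise ValidationError(
                f"response outside {{0,1,2,missing}} at row {row}")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def group_levels(self) -> list:
        return sorted(pd.unique(self.group).tolist(), key=str)

    @property
    def n_per_group(self) -> dict:
        return {g: int(np.sum(self.group == g)) for g in self.group_levels}

    def missing_mask(self) -> np.ndarray:
        return self.responses == MISSING

    def missing_proportion(self) -> pd.Series:
        """Per-item proportion of missing cells."""
        return pd.Series(self.missing_mask().mean(axis=0), index=self.items)

    def subset(self, group_label) -> "ItemResponseMatrix":
        sel = self.group == group_label
        if not sel.any():
            raise ValidationError(f"empty group {group_label!r}")
        return ItemResponseMatrix(self.responses[sel], self.group[sel], self.items)

    def reversed(self) -> "ItemResponseMatrix":
        """Return a copy with the reverse-scored items recoded x -> 2 - x."""
        resp = self.responses.copy()
        for item in REVERSE_SCORED:
            j = self.items.index(item)
            col = resp[:, j]
            obs = col != MISSING
            col[obs] = 2 - col[obs]
        return ItemResponseMatrix(resp, self.group.copy(), self.items)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=list(self.items))
        df = df.mask(df == MISSING)
        df = df.astype("Int64")
        df.insert(0, "group", self.group)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NA")


def load_item_responses(path, items: tuple[str, ...] = ITEM_ORDER,
                        group_col: str = "group") -> ItemResponseMatrix:
    """Read a delimited item-response table (CSV, header row, NA/empty = missing).

    Expects one row per person, one column per SDQ item plus a group column.
    Unknown or absent item columns raise a schema error; cell values outside
    {0, 1, 2, missing} raise a validation error naming the offending row.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    missing_cols = [c for c in items if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"item columns absent from file: {missing_cols}")
    if group_col not in df.columns:
        raise ValidationError(f"group column {group_col!r} absent from file")
    resp = df[list(items)].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = ~np.isnan(resp) & ~np.isin(resp, (0.0, 1.0, 2.0))
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise ValidationError(
            f"value outside {{0,1,2,NA}} at data row {row}")
    coded = np.where(np.isnan(resp), MISSING, resp).astype(np.int64)
    return ItemResponseMatrix(coded, df[group_col].to_numpy(), tuple(items))


def score_sdq(m: ItemResponseMatrix) -> pd.DataFrame:
    """Per-person subscale sums (0-10) and total difficulties (0-40).

    Reversal (x -> 2 - x) is applied internally to the five positively
    worded problem items. A person with any missing item within a subscale
    receives a missing score on that subscale; the total is missing if any
    of the four problem subscales is missing.
    """
    rev = m.reversed()
    df = pd.DataFrame(rev.responses, columns=list(m.items)).mask(
        rev.missing_mask())
    out = pd.DataFrame(index=df.index)
    for scale in SCALES:
        cols = scale_items(scale)
        out[scale] = df[cols].sum(axis=1, min_count=len(cols))
    out["total"] = out[list(PROBLEM_SCALES)].sum(axis=1, min_count=4)
    out.insert(0, "group", m.group)
    return out


def endorsement_table(m: ItemResponseMatrix, by_group: bool = True) -> pd.DataFrame:
    """Percent endorsing each category per item, over non-missing responses.

    Returns a frame indexed by item with columns (sample, category) where
    sample is ``full`` plus each group level when ``by_group``.
    """
    samples: dict[str, ItemResponseMatrix] = {"full": m}
    if by_group:
        for g in m.group_levels:
            samples[str(g)] = m.subset(g)
    blocks = {}
    for name, mat in samples.items():
        counts = np.stack([(mat.responses == k).sum(axis=0) for k in range(3)],
                          axis=1).astype(float)
        denom = counts.sum(axis=1, keepdims=True)
        if (denom == 0).any():
            raise ValidationError("item with no observed responses")
        blocks[name] = 100.0 * counts / denom
    cols = pd.MultiIndex.from_product(
        [list(samples), ["not_true", "somewhat_true", "certainly_true"]])
    data = np.concatenate([blocks[name] for name in samples], axis=1)
    return pd.DataFrame(data, index=list(m.items), columns=cols)
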