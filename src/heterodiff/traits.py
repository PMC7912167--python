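"""Mid-parent and high-parent heterosis statistics.

For a trait with hybrid mean :math:`M_{HY}`, mid-parent mean
:math:`M_{MiP} = (M_{FP} + M_{MP})/2` and high-parent mean
:math:`M_{HiP} = \\max(M_{FP}, M_{MP})`:

.. math::

    \\mathrm{MPH}\\,(\\%) = 100\\,(M_{HY} - M_{MiP}) / M_{MiP}

    \\mathrm{HPH}\\,(\\%) = 100\\,(M_{HY} - M_{HiP}) / M_{HiP}

For all-positive means ``MPH >= HPH`` always, since the mid-parent mean
can never exceed the high-parent mean.

Block-level uncertainty is propagated by recomputing both percentages
within each replicate block and taking the standard deviation across
blocks, so the reported SD reflects field-block variation rather than a
delta-method approximation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import TraitTable, TrioDesign, ValidationError

RESULT_COLUMNS = [
    "trio",
    "trait",
    "M_HY",
    "M_MiP",
    "M_HiP",
    "MPH",
    "HPH",
    "MPH_sd",
    "HPH_sd",
]


def _mph_hph(m_hy: float, m_fp: float, m_mp: float) -> tuple[float, float]:
    m_mip = (m_fp + m_mp) / 2.0
    m_hip = max(m_fp, m_mp)
    return (
        100.0 * (m_hy - m_mip) / m_mip,
        100.0 * (m_hy - m_hip) / m_hip,
    )


def heterosis_stats(traits: TraitTable, trios: list[TrioDesign]) -> pd.DataFrame:
    """Compute MPH and HPH per trio and trait, with across-block SDs.

    Raises if a line mean is non-positive or a trio line has no trait
    values.  Block SDs are NaN when fewer than two complete blocks exist.
    """
    df = traits.df
    rows = []
    for trio in trios:
        fp, mp, hy = trio.female_line, trio.male_line, trio.hybrid_line
        for trait in sorted(df["trait"].unique()):
            means = {}
            for line in (fp, mp, hy):
                means[line] = traits.line_mean(line, trait)
                if means[line] <= 0:
                    raise ValidationError(
                        f"non-positive mean for line {line!r}, trait {trait!r}"
                    )
            mph, hph = _mph_hph(means[hy], means[fp], means[mp])
            m_mip = (means[fp] + means[mp]) / 2.0
            m_hip = max(means[fp], means[mp])

            # per-block recomputation over blocks present for all three lines
            sub = df[df["trait"] == trait]
            pivot = sub.pivot_table(
                index="block", columns="line_id", values="value", aggfunc="mean"
            )
            per_block = pivot.dropna(subset=[fp, mp, hy]) if set(
                (fp, mp, hy)
            ) <= set(pivot.columns) else pd.DataFrame()
            if len(per_block) >= 2:
                vals = np.array(
                    [
                        _mph_hph(r[hy], r[fp], r[mp])
                        for _, r in per_block.iterrows()
                    ]
                )
                mph_sd = float(np.std(vals[:, 0], ddof=1))
                hph_sd = float(np.std(vals[:, 1], ddof=1))
            else:
                mph_sd = hph_sd = float("nan")

            rows.append(
                {
                    "trio": hy,
                    "trait": trait,
                    "M_HY": means[hy],
                    "M_MiP": m_mip,
                    "M_HiP": m_hip,
                    "MPH": mph,
                    "HPH": hph,
                    "MPH_sd": mph_sd,
                    "HPH_sd": hph_sd,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
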