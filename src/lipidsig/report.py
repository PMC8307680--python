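"""Run-level markdown report assembling the outputs of every pipeline stage.

The body is a deterministic function of the stage outputs, config and seed
(no timestamps), so identical runs produce byte-identical reports.
"""

from __future__ import annotations

from pathlib import Path


def _table_md(df, max_rows: int = 15) -> str:
    shown = df.head(max_rows)
    try:
        return shown.to_markdown(index=False)
    except ImportError:  # tabulate not installed
        return "```\n" + shown.to_string(index=False) + "\n```"


def build_report(
    policy=None,
    class_table=None,
    differential=None,
    presence=None,
    embedding=None,
    cv=None,
    config=None,
    seed=None,
    path=None,
) -> str:
    """Assemble a markdown report; sections for stages not run are marked
    absent.  Returns the report body; writes it to ``path`` when given."""
    lines = ["# Lipidomics panel analysis report", ""]
    if config is not None:
        lines += ["## Configuration", "", f"    {config!r}", ""]
    if seed is not None:
        lines += [f"Seed: `{seed}`", ""]

    lines += ["## Missingness policy", ""]
    if policy is None:
        lines += ["_Stage not run._", ""]
    else:
        lines += [
            f"- retained (all analyses): {len(policy.retained_all)} compounds",
            f"- retained (quantitative tier): {len(policy.retained_quant)} compounds",
            f"- excluded: {len(policy.excluded)} compounds",
            "",
        ]

    lines += ["## Lipid-class composition", ""]
    if class_table is None:
        lines += ["_Stage not run._", ""]
    else:
        pct = class_table[[c for c in class_table.columns if c.endswith("_pct")]]
        means = pct.mean(axis=0).sort_values(ascending=False)
        lines += ["Mean contribution to the total lipid amount per sample:", ""]
        lines += [f"- {name[:-4]}: {val:.1f}%" for name, val in means.items()]
        lines += [""]

    lines += ["## Differential abundance", ""]
    if differential is None:
        lines += ["_Stage not run._", ""]
    else:
        sig = differential.significant()
        n_omni = int((differential.omnibus["p"] < differential.model.config.alpha).sum())
        lines += [
            f"- compounds with omnibus p < "
            f"{differential.model.config.alpha}: {n_omni}",
            f"- gatekept pairwise findings: {len(sig)}",
            "",
            _table_md(differential.summary(top=5)[
                ["metabolite", "pair", "p", "q", "r", "fold_change", "omnibus_p"]
            ]),
            "",
        ]

    lines += ["## Presence/absence analysis", ""]
    if presence is None or len(presence) == 0:
        lines += ["_Stage not run._", ""]
    else:
        n_sig = int((presence["q"] < 0.05).sum())
        lines += [
            f"- excluded-tier compounds tested: {len(presence)}",
            f"- group-related at q < 0.05: {n_sig}",
            "",
        ]

    lines += ["## Global structure (2-D embedding)", ""]
    if embedding is None:
        lines += ["_Stage not run._", ""]
    else:
        lines += [
            f"- group silhouette in embedding space: {embedding.silhouette:.3f}",
            f"- parameters: {embedding.params}",
            "",
        ]

    lines += ["## Classification", ""]
    if cv is None:
        lines += ["_Stage not run._", ""]
    else:
        lines += ["```", cv.summary(), "```", ""]

    body = "\n".join(lines)
    if path is not None:
        Path(path).write_text(body, encoding="utf-8")
    return body
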