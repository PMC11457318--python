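"""iTOL DATASET_COLORSTRIP writer for coloring tree leaves by RGA class."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

#: Tree-figure convention: RPW8-NB-LRR red, TIR-NB-LRR blue, CC-NB-LRR yellow.
DEFAULT_CLASS_COLORS: Mapping[str, str] = {
    "RNL": "#ff0000",
    "TNL": "#0000ff",
    "CNL": "#ffff00",
    "RLK": "#008000",
    "RLP": "#800080",
    "LYSM": "#ff8c00",
    "PARTIAL": "#808080",
    "UNCLASSIFIED": "#c0c0c0",
}


def write_itol_colors(
    class_map: Mapping[str, str],
    path: str | Path | None = None,
    colors: Mapping[str, str] = DEFAULT_CLASS_COLORS,
    dataset_label: str = "RGA class",
) -> str:
    """Render (and optionally write) a DATASET_COLORSTRIP annotation file.

    ``class_map`` maps leaf label -> RGA class name; classes without a
    configured color fall back to grey.
    """
    lines = [
        "DATASET_COLORSTRIP",
        "SEPARATOR TAB",
        f"DATASET_LABEL\t{dataset_label}",
        "COLOR\t#000000",
        "DATA",
    ]
    for leaf in sorted(class_map):
        cls = str(class_map[leaf])
        lines.append(f"{leaf}\t{colors.get(cls, '#808080')}\t{cls}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
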