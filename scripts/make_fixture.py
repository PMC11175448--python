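"""Regenerate the bundled panel fixture files under src/panelscope/data/."""

from pathlib import Path

from panelscope.panel_fixture import PANEL_GENES, build_bundled_panel
from panelscope.panel_model import write_panel_bed


def main() -> None:
    data_dir = Path(__file__).resolve().parents[1] / "src" / "panelscope" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    panel = build_bundled_panel()
    write_panel_bed(panel, data_dir / "ird_panel.bed")
    with open(data_dir / "ird_panel_genes.tsv", "w") as fh:
        fh.write("# gene symbols of the bundled panel\n")
        for gene in PANEL_GENES:
            fh.write(gene + "\n")
    print(f"wrote {len(panel.regions)} regions, {len(panel.genes)} genes -> {data_dir}")


if __name__ == "__main__":
    main()
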