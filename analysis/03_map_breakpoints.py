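#!/usr/bin/env python
"""Localize the translocation breakpoints two ways and compare.

CNV route: pool the reference embryos' segment boundaries (with a fine-bin
refinement pass) into a windowed consensus per chromosome.  Split-read route:
quality-filter the long reads, cluster interchromosomal breakend pairs, and
report single-base junction coordinates.  Prints both estimates and their
distance per chromosome.
"""
import sys
from pathlib import Path

from click.testing import CliRunner

from pgtsr.cli import main as cli

OUT = Path(__file__).resolve().parent.parent / "results" / "work"


def run() -> None:
    res = CliRunner().invoke(cli, ["breakpoints", str(OUT)])
    sys.stdout.write(res.output)
    if res.exit_code:
        raise SystemExit(res.exit_code)


if __name__ == "__main__":
    run()
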