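#!/usr/bin/env python
"""Recompute the two pedigrees' published worked-example numbers from fixtures.

From the in-study karyotype strings and breakpoint coordinates alone (no
sequencing data): reference-embryo selection for both pedigrees, the four
windowed breakpoint localizations, the CNV-vs-split-read concordance
distances, and the whole-Mb size labels implied by the single-base
breakpoints.  Writes results/worked_examples.json.
"""
import sys
from pathlib import Path

from click.testing import CliRunner

from pgtsr.cli import main as cli

OUT = Path(__file__).resolve().parent.parent / "results" / "worked_examples.json"


def run() -> None:
    OUT.parent.mkdir(parents=True, exist_ok=True)
    res = CliRunner().invoke(cli, ["worked-examples", "--out", str(OUT)])
    sys.stdout.write(res.output)
    if res.exit_code:
        raise SystemExit(res.exit_code)
    print(f"summary -> {OUT}")


if __name__ == "__main__":
    run()
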