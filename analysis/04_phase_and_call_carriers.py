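#!/usr/bin/env python
"""Phase the derivative haplotypes and call carrier status.

Selects informative SNPs flanking the split-read breakpoints, phases which
carrier haplotype rides each derivative (independently from reference embryos
and from junction-spanning reads), calls every euploid embryo carrier or
non-carrier, and writes the full report bundle (karyotypes, breakpoints,
concordance, haplotype matrix, carrier calls) to results/work/report/.
"""
import sys
from pathlib import Path

from click.testing import CliRunner

from pgtsr.cli import main as cli

OUT = Path(__file__).resolve().parent.parent / "results" / "work"


def run() -> None:
    for cmd in (["phase", str(OUT)], ["report", str(OUT)]):
        res = CliRunner().invoke(cli, cmd)
        sys.stdout.write(res.output)
        if res.exit_code:
            raise SystemExit(res.exit_code)


if __name__ == "__main__":
    run()
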