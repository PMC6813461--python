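"""Bundle the run's tables into results/run/report/summary.txt."""

from common import RUN_DIR, config
from cytoforge.pipeline import run


def main() -> None:
    run(config(), ["report"], RUN_DIR)
    print((RUN_DIR / "report" / "summary.txt").read_text())


if __name__ == "__main__":
    main()
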