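"""Shared setup for the numbered analysis drivers."""

from pathlib import Path

from pgnet.pipeline import PipelineConfig, PipelineRunner

HERE = Path(__file__).resolve().parent
ROOT = HERE.parent


def runner() -> PipelineRunner:
    cfg = PipelineConfig.from_yaml(HERE / "config.yaml")
    cfg.out_dir = str(ROOT / cfg.out_dir)
    return PipelineRunner(cfg)
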