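import numpy as np
import pytest

from spsp import (
    DatasetManifest,
    ManifestEntry,
    Recording,
    SymbolSequence,
    write_manifest,
    write_recording,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_recording(rng):
    return Recording(
        subject_id="s01",
        trial_id="t01",
        label="calm",
        sample_rate_hz=128.0,
        channel_names=["ch01", "ch02", "ch03"],
        data=rng.standard_normal((3, 40)),
    )


def make_sequences(symbol_rows, labels, subjects, S):
    """Build SymbolSequence objects from parallel lists."""
    out = []
    for i, (row, label, subject) in enumerate(zip(symbol_rows, labels, subjects)):
        out.append(
            SymbolSequence(
                symbols=np.asarray(row, dtype=int),
                S=S,
                subject_id=subject,
                trial_id=f"t{i:02d}",
                label=label,
            )
        )
    return out


@pytest.fixture
def disk_dataset(tmp_path, rng):
    """A tiny 2-subject, 2-class dataset written to disk with a manifest."""
    entries = []
    for subject in ("s01", "s02"):
        for label in ("a", "b"):
            rec = Recording(
                subject_id=subject,
                trial_id=f"{label}01",
                label=label,
                sample_rate_hz=128.0,
                channel_names=[f"ch{i + 1:02d}" for i in range(4)],
                data=rng.standard_normal((4, 64)),
            )
            fname = f"{subject}_{label}01.csv"
            write_recording(rec, str(tmp_path / fname))
            entries.append(
                ManifestEntry(
                    file_path=fname,
                    subject_id=subject,
                    trial_id=f"{label}01",
                    label=label,
                )
            )
    manifest = DatasetManifest(entries=entries, channel_count=4, sample_rate_hz=128.0)
    manifest_path = tmp_path / "manifest.json"
    write_manifest(manifest, str(manifest_path))
    return manifest_path
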