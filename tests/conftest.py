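import gzip
import zipfile

import numpy as np
import pytest

from survscan.formats import GenotypeRecord, PhenotypeTable, write_gen


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_record(probs, snp_id="snp1", rs_id="rs1", position=1000,
                allele_a="A", allele_b="G", chromosome="1"):
    probs = np.asarray(probs, dtype=float)
    return GenotypeRecord(
        snp_id=snp_id, rs_id=rs_id, chromosome=chromosome,
        position_bp=position, allele_a=allele_a, allele_b=allele_b,
        source_kind="probabilities", probs=probs,
    )


def make_phenotypes(time, event, **covariates):
    import pandas as pd

    time = np.asarray(time, float)
    return PhenotypeTable(
        subject_ids=[f"id{i}" for i in range(len(time))],
        time=time,
        event=np.asarray(event, float),
        covariates=pd.DataFrame({k: np.asarray(v, float) for k, v in covariates.items()}),
    )


@pytest.fixture
def gen_file_factory(tmp_path):
    """Write GenotypeRecords to a .gen file, optionally gzip/zip compressed."""

    def factory(records, compression="none", name="data.gen"):
        plain = tmp_path / name
        write_gen(records, plain)
        if compression == "none":
            return plain
        raw = plain.read_bytes()
        if compression == "gzip":
            path = tmp_path / (name + ".gz")
            path.write_bytes(gzip.compress(raw))
            return path
        if compression == "zip":
            path = tmp_path / (name + ".zip")
            with zipfile.ZipFile(path, "w") as zf:
                zf.writestr(name, raw)
            return path
        raise ValueError(compression)

    return factory


@pytest.fixture
def sample_file_factory(tmp_path):
    def factory(lines, name="data.sample"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return factory
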