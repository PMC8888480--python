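"""Shared fixtures: synthetic libraries/datasets and a programmatic mzML builder."""

from __future__ import annotations

import base64
import struct
import zlib

import pytest
from hypothesis import HealthCheck, settings

from aglycon import (
    FixtureConfig,
    make_aglycone_library,
    make_glucuronide_dataset,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_cfg() -> FixtureConfig:
    return FixtureConfig(seed=7).noiseless()

@pytest.fixture(scope="session")
def noiseless_library(noiseless_cfg):
    return make_aglycone_library(noiseless_cfg)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_cfg, noiseless_library):
    return make_glucuronide_dataset(noiseless_library, noiseless_cfg)


@pytest.fixture(scope="session")
def noisy_cfg() -> FixtureConfig:
    return FixtureConfig(seed=11)


@pytest.fixture(scope="session")
def noisy_library(noisy_cfg):
    return make_aglycone_library(noisy_cfg)


@pytest.fixture(scope="session")
def noisy_dataset(noisy_cfg, noisy_library):
    return make_glucuronide_dataset(noisy_library, noisy_cfg)


# ---------------------------------------------------------------------------
# minimal mzML builder (text only, generated at test time)
# ---------------------------------------------------------------------------

def _encode(values, dtype="<d", compress=False):
    packed = struct.pack(f"{dtype[0]}{len(values)}{dtype[1]}", *values)
    if compress:
        packed = zlib.compress(packed)
    return base64.b64encode(packed).decode()


def mzml_spectrum(index, ms_level, rt_sec, mzs, intensities, precursor=None,
                  rt_unit="second", dtype="<d", compress=False):
    float_acc = "MS:1000523" if dtype == "<d" else "MS:1000521"
    float_name = "64-bit float" if dtype == "<d" else "32-bit float"
    comp_acc = "MS:1000574" if compress else "MS:1000576"
    comp_name = "zlib compression" if compress else "no compression"
    prec_xml = ""
    if precursor is not None:
        prec_xml = f"""
        <precursorList count="1"><precursor>
          <selectedIonList count="1"><selectedIon>
            <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{precursor}"/>
            <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="1"/>
          </selectedIon></selectedIonList>
        </precursor></precursorList>"""
    mz_b64 = _encode(mzs, dtype, compress)
    int_b64 = _encode(intensities, dtype, compress)
    return f"""
      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(mzs)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
        <scanList count="1"><scan>
          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_sec}" unitName="{rt_unit}"/>
        </scan></scanList>{prec_xml}
        <binaryDataArrayList count="2">
          <binaryDataArray>
            <cvParam cvRef="MS" accession="{float_acc}" name="{float_name}"/>
            <cvParam cvRef="MS" accession="{comp_acc}" name="{comp_name}"/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray>
            <cvParam cvRef="MS" accession="{float_acc}" name="{float_name}"/>
            <cvParam cvRef="MS" accession="{comp_acc}" name="{comp_name}"/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>"""


def mzml_document(spectra_xml: list[str]) -> str:
    return f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="run1">
    <spectrumList count="{len(spectra_xml)}">{''.join(spectra_xml)}
    </spectrumList>
  </run>
</mzML>"""
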