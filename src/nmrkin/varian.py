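"""Minimal reader/writer for the Varian/Agilent fid + procpar dialect.

A Varian acquisition directory holds a binary ``fid`` file (big-endian:
a 32-byte file header, then per-block 28-byte headers followed by
interleaved real/imaginary traces as int16, int32 or float32 depending
on status bits) and a text ``procpar`` file of named parameters.  Only
what the quantification chain needs is parsed: number of points,
spectral width, spectrometer frequency, timing and transient count.

The writer emits float32 data and a matching procpar; round-tripping
through it is exercised in the test suite, so synthetic acquisitions
can stand in for spectrometer output.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .nmr import FIDSeries

__all__ = ["read_varian", "write_varian", "read_procpar"]

_FILE_HEADER = struct.Struct(">6i2hi")    # nblocks ntraces np ebytes tbytes bbytes vers status nbheaders
_BLOCK_HEADER = struct.Struct(">4hi4f")   # scale status index mode ctcount lpval rpval lvl tlt

_S_FLOAT = 0x8
_S_32 = 0x4


def read_procpar(path) -> dict[str, list]:
    """Parse a procpar file into name -> list of values.

    Each parameter is a header line starting with its name, a line of
    ``count value value ...`` and a trailing enumeration line; string
    values are double-quoted and may span multiple lines (one per
    value).
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    params: dict[str, list] = {}
    i = 0
    while i < len(lines):
        head = lines[i].split()
        if not head or not head[0][0].isalpha():
            i += 1
            continue
        name = head[0]
        i += 1
        vals_line = lines[i].split()
        count = int(vals_line[0])
        raw = vals_line[1:]
        if raw and raw[0].startswith('"'):
            values = [raw_join.strip('"') for raw_join in
                      [" ".join(raw)]]
            while len(values) < count:
                i += 1
                values.append(lines[i].strip().strip('"'))
        else:
            values = []
            for tok in raw:
                try:
                    values.append(int(tok))
                except ValueError:
                    values.append(float(tok))
        i += 1  # skip the trailing enumeration line
        i += 1
        params[name] = values
    return params


def _first(params: dict, name: str, default=None):
    vals = params.get(name)
    if not vals:
        if default is None:
            raise KeyError(f"procpar parameter {name!r} missing")
        return default
    return vals[0]


def read_varian(directory) -> FIDSeries:
    """Read a fid/procpar directory into a :class:`FIDSeries`.

    Block timestamps are reconstructed from the acquisition timing:
    block k is centred at (k + 1/2)·nt·(at + d1) seconds.
    """
    directory = Path(directory)
    params = read_procpar(directory / "procpar")
    raw = (directory / "fid").read_bytes()

    nblocks, ntraces, npts, ebytes, tbytes, bbytes, _vers, status, nbheaders = \
        _FILE_HEADER.unpack_from(raw, 0)
    if status & _S_FLOAT:
        dtype = ">f4"
    elif status & _S_32:
        dtype = ">i4"
    else:
        dtype = ">i2"
    offset = _FILE_HEADER.size
    blocks = []
    for _ in range(nblocks):
        offset += _BLOCK_HEADER.size * nbheaders
        trace = np.frombuffer(raw, dtype=dtype, count=npts * ntraces,
                              offset=offset).astype(np.float64)
        offset += tbytes * ntraces
        trace = trace.reshape(ntraces, npts).sum(axis=0)  # sum stored traces
        blocks.append(trace[0::2] + 1j * trace[1::2])
    data = np.asarray(blocks)

    sw = float(_first(params, "sw"))
    sfrq = float(_first(params, "sfrq"))
    at = float(_first(params, "at", npts / 2 / sw))
    d1 = float(_first(params, "d1", 0.0))
    nt = int(_first(params, "nt", 1))
    pulse = float(_first(params, "pw90_angle", 90.0))
    tof_ppm = float(_first(params, "tof", 0.0)) / sfrq
    block_sec = nt * (at + d1)
    timestamps = (np.arange(nblocks) + 0.5) * block_sec / 60.0
    return FIDSeries(data=data, spectral_width=sw, spectrometer_freq=sfrq,
                     acquisition_time=at, relaxation_delay=d1,
                     pulse_angle=pulse, transients=nt,
                     timestamps_min=timestamps, carrier_ppm=tof_ppm)


def write_varian(fid: FIDSeries, directory) -> None:
    """Write a :class:`FIDSeries` as a float32 fid + procpar directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    npts = 2 * fid.n_points
    ebytes = 4
    tbytes = npts * ebytes
    bbytes = tbytes + _BLOCK_HEADER.size
    header = _FILE_HEADER.pack(fid.n_blocks, 1, npts, ebytes, tbytes, bbytes,
                               0, _S_FLOAT | 0x1, 1)
    chunks = [header]
    for b in range(fid.n_blocks):
        chunks.append(_BLOCK_HEADER.pack(0, _S_FLOAT | 0x1, b + 1, 0, 1,
                                         0.0, 0.0, 0.0, 0.0))
        inter = np.empty(npts, dtype=">f4")
        inter[0::2] = fid.data[b].real
        inter[1::2] = fid.data[b].imag
        chunks.append(inter.tobytes())
    (directory / "fid").write_bytes(b"".join(chunks))

    def par(name, value, partype=1):
        return (f"{name} {partype} 1 0 0 0 1 1 0 1 64\n"
                f"1 {value}\n0\n")

    procpar = "".join([
        par("sw", fid.spectral_width),
        par("sfrq", fid.spectrometer_freq),
        par("at", fid.acquisition_time),
        par("d1", fid.relaxation_delay),
        par("nt", fid.transients),
        par("np", npts),
        par("pw90_angle", fid.pulse_angle),
        par("tof", fid.carrier_ppm * fid.spectrometer_freq),
    ])
    (directory / "procpar").write_text(procpar)
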