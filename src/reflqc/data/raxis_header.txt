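# R-AXIS IV image plate, text fixture dialect (one record per line)
a3fPhi 0.0 0.0 1.0
a3fCircle 0.0 0.0 0.0
a2fXray1 1500.0
a2fXray2 1500.0
nPixels 3000 3000
fPixelSize 100.0
nIP_num 2
ImhCompression 8
a4cSpindle
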