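# Bruker PLATINUM CCD, text fixture dialect (one record per line)
ANGLES: 0.0 358.75 0.0 0.0
AXIS: 3
INCREME: 0.5
NPIXELB: 1
NEXP: 1 32
CCDPARM: 3.83 1.90 0.65 50.0 444.1
CENTER: 512.00 512.00
NROWS: 1024
NCOLS: 1024
PIXSIZE: 89.99
CORRECT:0138_1024_180s._fl
WARFIL:0138_1024_180s._ix
DARK: 0138_01024_00010._dk
MACH3: KAPPA-GONIOMETER
KAPPA: 0.0
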