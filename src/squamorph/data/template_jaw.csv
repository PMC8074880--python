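# Hand-authored 33-point template of a generalized squamate lower jaw in
# lateral view, anterior to the right, dorsal up; unit jaw length.
# Points 1-7 are the fixed landmarks (posterior articular, coronoid apex,
# ventral point below the coronoid, posterior-most tooth, ventral point below
# the tooth row, anterosuperior and anteroventral dentary tips); points 8-33
# are semilandmarks along the outline (dorsal posterior margin, coronoid
# descent, tooth row, then the ventral margin from tip back to articular).
x,y
0.00,0.06
0.22,0.30
0.22,-0.02
0.42,0.12
0.42,-0.03
1.00,0.10
1.00,0.01
0.05,0.10
0.10,0.16
0.15,0.23
0.19,0.28
0.26,0.27
0.31,0.20
0.37,0.15
0.50,0.12
0.60,0.12
0.70,0.11
0.80,0.11
0.88,0.10
0.95,0.10
0.95,0.00
0.88,-0.01
0.80,-0.02
0.72,-0.03
0.64,-0.03
0.56,-0.04
0.48,-0.04
0.34,-0.03
0.28,-0.02
0.16,-0.01
0.10,0.00
0.05,0.02
0.02,0.04
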