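label,Antigua,Nevis,Guanica,La Romana,Palisadores,Santiago,Trinidad,Pinar del Rio,Highlands,Lee Co.,Ayui
Nevis,0.012,,,,,,,,,,
Guanica,0.204,0.164,,,,,,,,,
La Romana,0.038,0.019,0.131,,,,,,,,
Palisadores,0.304,0.337,0.470,0.284,,,,,,,
Santiago,0.095,0.056,0.269,0.112,0.257,,,,,,
Trinidad,0.099,0.057,0.206,0.070,0.324,0.137,,,,,
Pinar del Rio,0.206,0.156,0.394,0.194,0.302,0.148,0.127,,,,
Highlands,0.166,0.122,0.265,0.101,0.397,0.193,0.127,0.232,,,
Lee Co.,0.114,0.092,0.436,0.097,0.426,0.110,0.095,0.076,0.100,,
Ayui,0.160,0.142,0.185,0.190,0.430,0.296,0.251,0.302,0.154,0.137,
Yuqueri,0.155,0.128,0.206,0.232,0.390,0.290,0.271,0.296,0.208,0.156,0.100
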