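label,country,status,lat,lon,n_diploid,registration
Antigua,Antigua,invaded,16.998,-61.75459,15,1958
Nevis,Nevis,invaded,17.11423,-62.54811,6,1957
Guanica,Puerto Rico,invaded,17.96472,-66.84639,24,1963
La Romana,Dominican Republic,invaded,18.4959,-68.98981,20,
Palisadores,Jamaica,invaded,17.942317,-76.762844,14,
Santiago,Cuba,invaded,19.96175,-75.68988,29,1980
Trinidad,Cuba,invaded,21.76201,-80.00963,30,
Pinar del Rio,Cuba,invaded,22.13986,-83.97028,30,
Highlands,Florida (USA),invaded,27.46667,-81.447,15,1990
Lee Co.,Florida (USA),invaded,26.451417,-82.1232,2,
Ayui,Argentina,native,-31.19545,-58.04662,24,
Yuqueri,Argentina,native,-31.38195,-58.128863,20,
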