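pattern,k
OXOOOO,-0.5470
OXOOOX,-1.2501
OXOOXO,0.3720
OXOOXX,-0.1687
OXOXOO,0.0215
OXOXOX,-0.5000
OXOXXO,1.1687
OXOXXX,0.6108
OXXOOO,-0.2959
OXXOOX,-0.8313
OXXOXO,0.8313
OXXOXX,0.2959
OXXXOO,0.5000
OXXXOX,-0.0431
OXXXXO,1.6034
OXXXXX,0.8931
XOOOOO,-0.8931
XOOOOX,-1.6034
XOOOXO,0.0431
XOOOXX,-0.5000
XOOXOO,-0.2959
XOOXOX,-0.8313
XOOXXO,0.8313
XOOXXX,0.2959
XOXOOO,-0.6108
XOXOOX,-1.1687
XOXOXO,0.5000
XOXOXX,-0.0215
XOXXOO,0.1687
XOXXOX,-0.3720
XOXXXO,1.2501
XOXXXX,0.5470
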