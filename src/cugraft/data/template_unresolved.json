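{
  "AmoA": {
    "3RGB": {"unresolved": [[1, 6], [192, 212], [246, 247]], "length": 247},
    "6CXH": {"unresolved": [[1, 3], [245, 247]], "length": 247},
    "4PHZ": {"unresolved": [[1, 8]], "length": 252},
    "4PI0": {"unresolved": [[1, 8]], "length": 252},
    "4PI2": {"unresolved": [[1, 8]], "length": 252},
    "3RFR": {"unresolved": [[1, 10]], "length": 252},
    "3CHX": {"unresolved": [[1, 11], [250, 252]], "length": 252}
  },
  "AmoB": {
    "3RGB": {"unresolved": [[1, 32]], "length": 414},
    "6CXH": {"unresolved": [[1, 32]], "length": 414},
    "4PHZ": {"unresolved": [[1, 28], [417, 420]], "length": 420},
    "4PI0": {"unresolved": [[1, 28], [419, 420]], "length": 420},
    "4PI2": {"unresolved": [[1, 28], [419, 420]], "length": 420},
    "3RFR": {"unresolved": [[1, 28], [415, 419]], "length": 419},
    "3CHX": {"unresolved": [[1, 40], [284, 294], [318, 327], [347, 350], [427, 431]], "length": 431}
  },
  "AmoC": {
    "3RGB": {"unresolved": [[1, 44], [225, 253], [287, 289]], "length": 289},
    "6CXH": {"unresolved": [[1, 89], [123, 156], [193, 218]], "length": 250},
    "4PHZ": {"unresolved": [[1, 15], [138, 165], [198, 225]], "length": 256},
    "4PI0": {"unresolved": [[1, 18], [200, 223]], "length": 256},
    "4PI2": {"unresolved": [[1, 15], [211, 223]], "length": 256},
    "3RFR": {"unresolved": [[1, 15], [198, 225]], "length": 256},
    "3CHX": {"unresolved": [[1, 17], [177, 256]], "length": 256}
  }
}
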